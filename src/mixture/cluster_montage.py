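"""K-means clustering of tile features and montage rendering for review.

Tiles embedded by the feature extractor are grouped with K-means (one model
per magnification). For each cluster a montage — a grid of randomly sampled
tile thumbnails — is rendered so a pathologist can judge what the cluster
depicts and pick the working number of clusters. ``assign_nearest`` is also
the non-integrated baseline: new tiles are labeled by their nearest training
centroid without any human integration step.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger("mixture.cluster")

__all__ = ["ClusterModel", "MontageConfig", "fit_kmeans", "assign_nearest",
           "build_montage", "sweep_k", "DEFAULT_K_SWEEP"]

#: candidate cluster counts offered for human selection
DEFAULT_K_SWEEP = [5, 8, 10, 30, 50, 80, 100, 120]


@dataclasses.dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray          # (k, feature_dim)
    assignments: np.ndarray        # training tile -> cluster id
    inertia: float
    seed: int

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.save(path.with_suffix(".centroids.npy"), self.centroids)
        path.with_suffix(".json").write_text(json.dumps(
            {"k": self.k, "seed": self.seed, "inertia": self.inertia}))
        pd.DataFrame({"tile_index": np.arange(len(self.assignments)),
                      "cluster_id": self.assignments}
                     ).to_csv(path.with_suffix(".assignments.tsv"), sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cents = np.load(path.with_suffix(".centroids.npy"))
        assign = pd.read_csv(path.with_suffix(".assignments.tsv"),
                             sep="\t")["cluster_id"].to_numpy()
        return cls(k=meta["k"], centroids=cents, assignments=assign,
                   inertia=meta["inertia"], seed=meta["seed"])


@dataclasses.dataclass
class MontageConfig:
    tiles_per_montage: int = 120
    grid_cols: int = 12
    thumbnail_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.tiles_per_montage < 1 or self.grid_cols < 1:
            raise ValueError("tiles_per_montage and grid_cols must be >= 1")


def _features_of(features) -> np.ndarray:
    return features.values if hasattr(features, "values") else np.asarray(features)


def fit_kmeans(features, k: int, seed: int = 0, n_restarts: int = 10
               ) -> ClusterModel:
    """K-means with k-means++ init and ``n_restarts`` restarts.

    Stored assignments are re-derived from the final centroids so that
    ``assign_nearest`` on the training features reproduces them exactly.
    """
    x = _features_of(features)
    if len(x) < k:
        raise ValueError(f"need at least k={k} samples, got {len(x)}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts,
                random_state=seed & 0x7FFFFFFF).fit(x)
    model = ClusterModel(k=k, centroids=km.cluster_centers_.astype(np.float64),
                         assignments=np.empty(0, dtype=int),
                         inertia=float(km.inertia_), seed=seed)
    model.assignments = assign_nearest(model, x)
    return model


def assign_nearest(model: ClusterModel, features) -> np.ndarray:
    """Nearest-centroid labels; ties resolved to the lowest cluster id."""
    x = _features_of(features)
    if x.shape[1] != model.centroids.shape[1]:
        raise ValueError(f"feature dim {x.shape[1]} does not match "
                         f"centroid dim {model.centroids.shape[1]}")
    # squared Euclidean distances; argmin picks the lowest index on ties
    d2 = (np.sum(x.astype(np.float64) ** 2, axis=1, keepdims=True)
          - 2.0 * x.astype(np.float64) @ model.centroids.T
          + np.sum(model.centroids ** 2, axis=1))
    return np.argmin(np.round(d2, 9), axis=1)


def build_montage(tileset, assignments: np.ndarray, cluster_id: int,
                  config: MontageConfig):
    """Montage image + legend for one cluster.

    Thumbnails are a uniform without-replacement sample of the cluster's
    tiles, laid out row-major on a ``grid_cols``-wide grid; the legend lists
    tile keys in grid order.
    """
    assignments = np.asarray(assignments)
    member_idx = np.flatnonzero(assignments == cluster_id)
    if len(member_idx) == 0:
        logger.warning("cluster %d is empty; emitting empty montage", cluster_id)
        return np.zeros((0, 0, 3), dtype=np.uint8), []
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, cluster_id])
    n_take = min(config.tiles_per_montage, len(member_idx))
    chosen = rng.choice(member_idx, size=n_take, replace=False)
    ts = config.thumbnail_size
    cols = config.grid_cols
    rows = int(np.ceil(n_take / cols))
    canvas = np.zeros((rows * ts, cols * ts, 3), dtype=np.uint8)
    legend = []
    for pos, idx in enumerate(chosen):
        tile = tileset[int(idx)]
        thumb = np.asarray(Image.fromarray(tile.image).resize((ts, ts), Image.BILINEAR))
        r, c = divmod(pos, cols)
        canvas[r * ts:(r + 1) * ts, c * ts:(c + 1) * ts] = thumb
        legend.append(tile.key)
    return canvas, legend


def sweep_k(features, k_list=None, seed: int = 0) -> tuple:
    """Fit one model per candidate k and summarise inertia + silhouette.

    The summary table supports the human choice of the working cluster
    count; silhouette is computed on a <= 5000-row subsample for large n.
    """
    if k_list is None:
        k_list = DEFAULT_K_SWEEP
    x = _features_of(features)
    models, rows = {}, []
    for k in k_list:
        model = fit_kmeans(x, k, seed=seed)
        models[k] = model
        sil = np.nan
        if 1 < k < len(x):
            sub = np.arange(len(x))
            if len(x) > 5000:
                sub = np.random.default_rng(seed).choice(len(x), 5000, replace=False)
            labels = model.assignments[sub]
            if len(np.unique(labels)) > 1:
                sil = float(silhouette_score(x[sub], labels))
        rows.append({"k": k, "inertia": model.inertia, "silhouette": sil})
    return models, pd.DataFrame(rows)
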