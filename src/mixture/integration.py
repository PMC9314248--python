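"""Cluster integration: turning reviewed clusters into labeled tile data.

"Cluster integration" is the human-in-the-loop step: pathologists view the
per-cluster montages and merge clusters depicting the same morphological
finding into one named class; clusters that mix more than one finding are
EXCLUDED; clusters that fit no finding go to "other". The decision is
recorded as a JSON integration map — a reviewable, diffable artifact — and
applied mechanically to produce a labeled tile dataset for transfer
learning. Supplemental per-case clustering enriches rare findings (e.g.
fibroblastic foci) and a corrections file captures the ~10% manual
relabeling pass.

Default finding schemes per magnification:

* 2.5x: acellular fibrosis, cellular fibrosis, near normal, other
* 5x:   acellular fibrosis, edge, cellular and fibrotic IP,
        cellular IP/NSIP, lymphoid follicle, complete normal, pale, other
* 20x:  dense fibrosis, elastosis, fibroblastic foci, fat, mucin,
        bronchiolar epithelium, lymphocyte aggregation, other

"complete normal" at 5x is special: its tiles are excluded from the
case-level frequency denominator downstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster_montage import MontageConfig, build_montage, fit_kmeans

logger = logging.getLogger("mixture.integration")

__all__ = ["EXCLUDED", "FindingScheme", "IntegrationMap", "LabeledTileDataset",
           "default_scheme", "load_integration_map", "save_integration_map",
           "build_labeled_dataset", "enrich_per_case", "apply_corrections",
           "oracle_integration_map"]

#: sentinel for clusters dropped from training (mixed-finding clusters)
EXCLUDED = "EXCLUDED"

_DEFAULT_SCHEMES = {
    "2.5x": ["acellular fibrosis", "cellular fibrosis", "near normal", "other"],
    "5x": ["acellular fibrosis", "edge", "cellular and fibrotic IP",
           "cellular IP/NSIP", "lymphoid follicle", "complete normal",
           "pale", "other"],
    "20x": ["dense fibrosis", "elastosis", "fibroblastic foci", "fat",
            "mucin", "bronchiolar epithelium", "lymphocyte aggregation",
            "other"],
}


@dataclasses.dataclass(frozen=True)
class FindingScheme:
    magnification_level: str
    class_names: tuple

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if "other" not in self.class_names:
            raise ValueError('scheme must include an "other" class')

    @property
    def special_excluded_from_frequencies(self) -> tuple:
        return ("complete normal",) if "complete normal" in self.class_names else ()

    def index(self, name: str) -> int:
        return self.class_names.index(name)


def default_scheme(level: str) -> FindingScheme:
    if level not in _DEFAULT_SCHEMES:
        raise ValueError(f"no default scheme for level {level!r}")
    return FindingScheme(level, tuple(_DEFAULT_SCHEMES[level]))


@dataclasses.dataclass
class IntegrationMap:
    scheme: FindingScheme
    entries: dict                      # cluster_id (int) -> class name or EXCLUDED
    note: str = ""

    def validate(self, n_clusters: int) -> None:
        ids = sorted(self.entries)
        missing = [i for i in range(n_clusters) if i not in self.entries]
        if missing:
            raise ValueError(f"integration map missing cluster ids: {missing}")
        extra = [i for i in ids if not 0 <= i < n_clusters]
        if extra:
            raise ValueError(f"integration map has unknown cluster ids: {extra}")
        bad = sorted({v for v in self.entries.values()
                      if v != EXCLUDED and v not in self.scheme.class_names})
        if bad:
            raise ValueError(f"classes not in scheme: {bad}")

    def label_of(self, cluster_id: int) -> str:
        return self.entries[int(cluster_id)]


def save_integration_map(imap: IntegrationMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"magnification_level": imap.scheme.magnification_level,
               "classes": list(imap.scheme.class_names),
               "note": imap.note,
               "entries": {str(k): v for k, v in sorted(imap.entries.items())}}
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_integration_map(path: str | Path, cluster_model, scheme: FindingScheme
                         ) -> IntegrationMap:
    """Load and validate a map against a cluster model and scheme.

    Rejects duplicate cluster ids, missing ids, ids outside [0, k) and class
    names absent from the scheme.
    """
    raw = json.loads(Path(path).read_text())
    entries = {}
    for key, val in raw["entries"].items():
        cid = int(key)
        if cid in entries:
            raise ValueError(f"duplicate cluster id {cid} in {path}")
        entries[cid] = val
    imap = IntegrationMap(scheme=scheme, entries=entries, note=raw.get("note", ""))
    imap.validate(cluster_model.k)
    return imap


@dataclasses.dataclass
class LabeledTileDataset:
    """Tiles with finding labels, ready for transfer learning."""
    tile_keys: list                    # hashable tile identifiers
    images: np.ndarray                 # (n, ts, ts, 3) uint8
    labels: list                       # class names, in scheme
    sources: list                      # {principal, supplemental, correction}
    scheme: FindingScheme

    def __post_init__(self):
        n = len(self.tile_keys)
        if not (len(self.labels) == len(self.sources) == n == len(self.images)):
            raise ValueError("dataset fields must align")
        if len(set(self.tile_keys)) != n:
            raise ValueError("duplicate tile ids in labeled dataset")
        bad = {l for l in self.labels if l not in self.scheme.class_names}
        if bad:
            raise ValueError(f"labels not in scheme: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.tile_keys)

    def class_counts(self) -> dict:
        counts = {c: 0 for c in self.scheme.class_names}
        for l in self.labels:
            counts[l] += 1
        return counts

    def label_indices(self) -> np.ndarray:
        return np.array([self.scheme.index(l) for l in self.labels])

    def merged_with(self, other: "LabeledTileDataset") -> "LabeledTileDataset":
        if other.scheme.class_names != self.scheme.class_names:
            raise ValueError("cannot merge datasets with different schemes")
        return LabeledTileDataset(
            tile_keys=self.tile_keys + other.tile_keys,
            images=np.concatenate([self.images, other.images]) if len(other)
            else self.images,
            labels=self.labels + other.labels,
            sources=self.sources + other.sources,
            scheme=self.scheme)


def build_labeled_dataset(tileset, assignments: np.ndarray, imap: IntegrationMap,
                          source: str = "principal") -> LabeledTileDataset:
    """Label tiles with their cluster's integrated class; drop EXCLUDED ones."""
    assignments = np.asarray(assignments)
    if len(assignments) != len(tileset):
        raise ValueError("assignments must cover the tileset")
    keys, imgs, labels = [], [], []
    for i, tile in enumerate(tileset):
        cls = imap.label_of(assignments[i])
        if cls == EXCLUDED:
            continue
        keys.append(tile.key)
        imgs.append(tile.image)
        labels.append(cls)
    if not keys:
        logger.warning("all clusters excluded; labeled dataset is empty")
        ts = tileset.config.tile_size if hasattr(tileset, "config") else 0
        return LabeledTileDataset([], np.empty((0, ts, ts, 3), dtype=np.uint8),
                                  [], [], imap.scheme)
    return LabeledTileDataset(keys, np.stack(imgs), labels,
                              [source] * len(keys), imap.scheme)


def enrich_per_case(supplemental_tilesets: dict, encoder, k_per_case: int = 10,
                    seed: int = 0, montage_config: MontageConfig | None = None):
    """Cluster each supplemental case independently and emit montages.

    Returns ``(models, montages)`` keyed by case id. Cases with fewer tiles
    than ``k_per_case`` are skipped with a warning. The reviewed per-case
    maps are applied with :func:`build_labeled_dataset` (source
    ``supplemental``) and merged into the master dataset.
    """
    from .ssl_encoder import extract_features
    montage_config = montage_config or MontageConfig(seed=seed)
    models, montages = {}, {}
    for case_id, ts in supplemental_tilesets.items():
        if len(ts) < k_per_case:
            logger.warning("case %s has %d tiles < k=%d; skipped",
                           case_id, len(ts), k_per_case)
            continue
        feats = extract_features(encoder, ts)
        model = fit_kmeans(feats, k_per_case, seed=seed)
        models[case_id] = model
        montages[case_id] = {
            c: build_montage(ts, model.assignments, c, montage_config)
            for c in range(k_per_case)}
    return models, montages


def apply_corrections(dataset: LabeledTileDataset, corrections: pd.DataFrame | str | Path
                      ) -> tuple:
    """Apply a manual-correction table; returns (new_dataset, audit_log).

    Corrections are rows of (tile_id, action, new_class) with action
    ``relabel`` or ``remove``. Unknown tile ids raise.
    """
    if not isinstance(corrections, pd.DataFrame):
        corrections = pd.read_csv(corrections, sep="\t",
                                  converters={"tile_id": str})
    index = {str(k): i for i, k in enumerate(dataset.tile_keys)}
    labels = list(dataset.labels)
    sources = list(dataset.sources)
    drop = set()
    audit = []
    for _, row in corrections.iterrows():
        tid = str(row["tile_id"])
        if tid not in index:
            raise ValueError(f"correction references unknown tile id {tid!r}")
        i = index[tid]
        action = row["action"]
        if action == "remove":
            drop.add(i)
            audit.append({"tile_id": tid, "action": "remove",
                          "old": labels[i], "new": None})
        elif action == "relabel":
            new = row["new_class"]
            if new not in dataset.scheme.class_names:
                raise ValueError(f"new_class {new!r} not in scheme")
            audit.append({"tile_id": tid, "action": "relabel",
                          "old": labels[i], "new": new})
            labels[i] = new
            sources[i] = "correction"
        else:
            raise ValueError(f"unknown correction action {action!r}")
    keep = [i for i in range(len(dataset)) if i not in drop]
    new = LabeledTileDataset(
        [dataset.tile_keys[i] for i in keep], dataset.images[keep],
        [labels[i] for i in keep], [sources[i] for i in keep], dataset.scheme)
    return new, pd.DataFrame(audit, columns=["tile_id", "action", "old", "new"])


def oracle_integration_map(assignments: np.ndarray, true_labels: np.ndarray,
                           scheme: FindingScheme, class_names: list | None = None,
                           purity_threshold: float = 0.0) -> IntegrationMap:
    """Integration map from ground truth: each cluster -> its majority class.

    A stand-in for the pathologist on synthetic data. ``class_names`` maps
    integer truth labels to scheme class names (defaults to the scheme order).
    Clusters whose majority class covers less than ``purity_threshold`` of
    members are EXCLUDED, mirroring the mixed-finding rule.
    """
    assignments = np.asarray(assignments)
    true_labels = np.asarray(true_labels)
    names = class_names or list(scheme.class_names)
    entries = {}
    for cid in range(int(assignments.max()) + 1 if len(assignments) else 0):
        members = true_labels[assignments == cid]
        if len(members) == 0:
            entries[cid] = EXCLUDED
            continue
        counts = np.bincount(members)
        top = int(counts.argmax())
        purity = counts[top] / len(members)
        entries[cid] = names[top] if purity >= purity_threshold else EXCLUDED
    return IntegrationMap(scheme=scheme, entries=entries,
                          note="oracle majority-class integration")
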