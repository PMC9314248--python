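"""Transfer-learned finding classifiers and slide-aligned finding maps.

A fully connected head is added on top of the trained feature extractor and
the whole network (head plus all convolution filters, unless frozen) is
fine-tuned with cross-entropy on the integrated labels. Classified tiles
are rendered as a colour-coded grid ("finding map") aligned with the slide
tiling so the prediction can be compared side by side with the image.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .integration import FindingScheme, LabeledTileDataset
from .nn import Adam, softmax
from .ssl_encoder import Encoder, augment, preprocess_images

logger = logging.getLogger("mixture.classifier")

__all__ = ["ClassifierConfig", "FindingClassifier", "FindingMap",
           "train_classifier", "classify_tiles", "render_finding_map",
           "default_palette", "EMPTY"]

#: grid value for positions with no tile (background-excluded or absent)
EMPTY = "__empty__"

_NEUTRAL_RGB = (235, 235, 235)

_PALETTE_CYCLE = [
    (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
    (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
    (210, 245, 60), (170, 110, 40), (0, 0, 128), (128, 128, 0),
]


def default_palette(scheme: FindingScheme) -> dict:
    """Distinct colour per scheme class (wraps after 12 classes)."""
    return {name: _PALETTE_CYCLE[i % len(_PALETTE_CYCLE)]
            for i, name in enumerate(scheme.class_names)}


@dataclasses.dataclass
class ClassifierConfig:
    learning_rate: float = 1e-4
    fine_tune_all_layers: bool = True
    epochs: int = 10
    batch_size: int = 64
    augment_training: bool = False
    rotation_range: float = 20.0
    # stain-augmentation amplitude: random per-image channel gain 1 +/- cj and
    # brightness shift during fine-tuning, teaching invariance to slide-level
    # staining variation; 0 disables
    color_jitter: float = 0.3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


class FindingClassifier:
    """Encoder-initialised backbone + fresh fully connected head."""

    def __init__(self, encoder: Encoder, scheme: FindingScheme, seed: int = 0):
        self.net = encoder.net.copy()
        self.ssl_config = encoder.config
        self.scheme = scheme
        rng = np.random.default_rng(seed)
        d = encoder.config.feature_dim
        n_cls = len(scheme.class_names)
        self.Wh = (rng.standard_normal((n_cls, d)) * np.sqrt(1.0 / d)).astype(np.float32)
        self.bh = np.zeros(n_cls, dtype=np.float32)
        self.history: dict = {"loss": [], "val_accuracy": []}
        self.provenance: dict = {}

    # -- inference ----------------------------------------------------------
    def _features_raw(self, images: np.ndarray) -> np.ndarray:
        x = preprocess_images(images, self.ssl_config.crop_size,
                              self.ssl_config.input_size)
        z, _ = self.net.forward(x)
        return z

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        images = np.asarray(images)
        out = []
        for i in range(0, len(images), batch_size):
            z = self._features_raw(images[i:i + batch_size])
            out.append(softmax(z @ self.Wh.T + self.bh, axis=1))
        return np.concatenate(out) if out else np.empty((0, len(self.scheme.class_names)))

    def predict(self, images: np.ndarray, batch_size: int = 256):
        p = self.predict_proba(images, batch_size)
        idx = p.argmax(axis=1)          # argmax takes the first class on ties
        return [self.scheme.class_names[i] for i in idx], p

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        import json
        from pathlib import Path
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        params = self.net.params() + [self.Wh, self.bh]
        np.savez(path.with_suffix(".npz"), **{f"p{i}": p for i, p in enumerate(params)})
        path.with_suffix(".json").write_text(json.dumps({
            "level": self.scheme.magnification_level,
            "classes": list(self.scheme.class_names),
            "ssl_config": dataclasses.asdict(self.ssl_config),
            "provenance": self.provenance}, default=str))

    @classmethod
    def load(cls, path, encoder_config=None) -> "FindingClassifier":
        import json
        from pathlib import Path
        from .ssl_encoder import SSLConfig
        from .nn import ConvNet
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgd = dict(meta["ssl_config"])
        if isinstance(cfgd["backbone_channels"], str):
            cfgd["backbone_channels"] = tuple(
                int(c) for c in cfgd["backbone_channels"].strip("()").split(",")
                if c.strip())
        else:
            cfgd["backbone_channels"] = tuple(cfgd["backbone_channels"])
        for key in ("queue_size", "batch_size", "epochs", "feature_dim",
                    "crop_size", "input_size", "seed"):
            cfgd[key] = int(cfgd[key])
        for key in ("key_momentum", "temperature", "learning_rate",
                    "rotation_range"):
            cfgd[key] = float(cfgd[key])
        ssl_cfg = SSLConfig(**cfgd)
        net = ConvNet(3, ssl_cfg.backbone_channels, ssl_cfg.feature_dim,
                      ssl_cfg.input_size)
        with np.load(path.with_suffix(".npz")) as data:
            params = [data[f"p{i}"] for i in range(len(data.files))]
        scheme = FindingScheme(meta["level"], tuple(meta["classes"]))
        from .ssl_encoder import Encoder
        enc = Encoder(net, ssl_cfg)
        obj = cls(enc, scheme)
        obj.net.set_params(params[:-2])
        obj.Wh, obj.bh = params[-2].astype(np.float32), params[-1].astype(np.float32)
        obj.provenance = meta.get("provenance", {})
        return obj


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_val = int(np.floor(val_fraction * len(idx)))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


def train_classifier(encoder: Encoder, dataset: LabeledTileDataset,
                     config: ClassifierConfig) -> FindingClassifier:
    """Fine-tune a finding classifier on integrated labels.

    Cross-entropy loss, Adam optimiser. With ``fine_tune_all_layers`` the
    gradient flows into every backbone parameter; otherwise only the head
    is updated. An internal 90/10 stratified split provides a held-out
    accuracy trajectory for diagnostics.
    """
    if len(dataset) == 0:
        raise ValueError("labeled dataset is empty")
    y_all = dataset.label_indices()
    if len(np.unique(y_all)) < 2:
        raise ValueError("need at least two classes to train a classifier")
    rng = np.random.default_rng(config.seed)
    clf = FindingClassifier(encoder, dataset.scheme, seed=int(rng.integers(2**31)))
    backbone_before = None
    if not config.fine_tune_all_layers:
        backbone_before = [p.copy() for p in clf.net.params()]
    head_params = [clf.Wh, clf.bh]
    opt_head = Adam(head_params, lr=config.learning_rate)
    opt_bb = Adam(clf.net.params(), lr=config.learning_rate)
    tr, va = _stratified_split(y_all, config.validation_fraction, rng)
    images, cs = dataset.images, clf.ssl_config.crop_size
    for _ in range(config.epochs):
        order = rng.permutation(tr)
        losses = []
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            if config.augment_training:
                seeds = rng.integers(2**31, size=len(idx))
                batch = np.stack([
                    augment(images[i], seeds[j], config.rotation_range,
                            min(cs, images[i].shape[0]))
                    for j, i in enumerate(idx)])
            else:
                batch = images[idx]
            if config.color_jitter > 0:
                cj = config.color_jitter
                gains = rng.uniform(1 - cj, 1 + cj, size=(len(idx), 1, 1, 3))
                offs = rng.uniform(-cj, cj, size=(len(idx), 1, 1, 1)) * 90.0
                batch = np.clip(batch.astype(np.float32) * gains + offs,
                                0, 255).astype(np.uint8)
            x = preprocess_images(batch, cs, clf.ssl_config.input_size)
            z, cache = clf.net.forward(x, train=True)
            logits = z @ clf.Wh.T + clf.bh
            p = softmax(logits, axis=1)
            y = y_all[idx]
            b = len(idx)
            losses.append(float(-np.log(p[np.arange(b), y] + 1e-12).mean()))
            dlogits = p.copy()
            dlogits[np.arange(b), y] -= 1.0
            dlogits /= b
            g_head = [dlogits.T @ z, dlogits.sum(axis=0)]
            opt_head.step(head_params, [g.astype(np.float32) for g in g_head])
            if config.fine_tune_all_layers:
                dz = (dlogits @ clf.Wh).astype(np.float32)
                opt_bb.step(clf.net.params(), clf.net.backward(dz, cache))
        clf.history["loss"].append(float(np.mean(losses)) if losses else np.nan)
        if len(va):
            pred, _ = clf.predict(images[va])
            acc = float(np.mean([dataset.scheme.index(l) == y_all[i]
                                 for l, i in zip(pred, va)]))
        else:
            acc = np.nan
        clf.history["val_accuracy"].append(acc)
    if backbone_before is not None:
        clf.net.set_params(backbone_before)   # guarantee bit-identical backbone
    clf.provenance = {"n_tiles": len(dataset),
                      "classes": list(dataset.scheme.class_names),
                      "config": dataclasses.asdict(config)}
    return clf


def classify_tiles(classifier: FindingClassifier, tileset, batch_size: int = 256):
    """Per-tile predicted class + probability vector (rows sum to 1)."""
    images = (tileset.images() if hasattr(tileset, "images")
              else np.asarray(tileset))
    if len(images) == 0:
        return [], np.empty((0, len(classifier.scheme.class_names)))
    return classifier.predict(images, batch_size=batch_size)


@dataclasses.dataclass
class FindingMap:
    slide_id: str
    level: str
    label_grid: list                  # rows of class names / EMPTY
    image: np.ndarray                 # rendered RGB map

    def decode(self, palette: dict, cell_size: int) -> list:
        """Recover the label grid from the rendered image (exact colours)."""
        inv = {tuple(v): k for k, v in palette.items()}
        inv[_NEUTRAL_RGB] = EMPTY
        rows = []
        for r in range(len(self.label_grid)):
            row = []
            for c in range(len(self.label_grid[0])):
                px = tuple(int(v) for v in
                           self.image[r * cell_size, c * cell_size])
                row.append(inv[px])
            rows.append(row)
        return rows


def render_finding_map(tileset, labels, palette: dict, cell_size: int = 8
                       ) -> FindingMap:
    """Paint each tile's grid cell with its class colour.

    Grid positions without a tile are painted a neutral grey. Output size is
    (grid rows x cell_size, grid cols x cell_size).
    """
    tiles = list(tileset)
    if len(tiles) != len(labels):
        raise ValueError("labels must cover the tileset")
    missing = sorted({l for l in labels if l not in palette})
    if missing:
        raise ValueError(f"palette missing classes: {missing}")
    if not tiles:
        logger.warning("empty tileset; rendering zero-size map")
        return FindingMap("", "", [], np.zeros((0, 0, 3), dtype=np.uint8))
    n_rows = max(t.grid_row for t in tiles) + 1
    n_cols = max(t.grid_col for t in tiles) + 1
    grid = [[EMPTY] * n_cols for _ in range(n_rows)]
    img = np.empty((n_rows * cell_size, n_cols * cell_size, 3), dtype=np.uint8)
    img[:] = _NEUTRAL_RGB
    for tile, label in zip(tiles, labels):
        grid[tile.grid_row][tile.grid_col] = label
        r, c = tile.grid_row, tile.grid_col
        img[r * cell_size:(r + 1) * cell_size,
            c * cell_size:(c + 1) * cell_size] = palette[label]
    return FindingMap(tiles[0].slide_id, tiles[0].level, grid, img)
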