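"""Momentum-contrast self-supervised training of the tile feature extractor.

The elementary feature extractor ("ElEx") maps a tile to an L2-normalized
128-dimensional vector. It is trained without labels by momentum contrast:
two random augmentations of the same tile form a (query, positive-key)
pair; a FIFO queue of size K holds embeddings of past keys as negatives;
the key encoder is a momentum-blended copy of the query encoder
(theta_k <- m * theta_k + (1 - m) * theta_q); and the loss is InfoNCE, a
softmax cross-entropy over the positive and the K negative similarities
scaled by a temperature t.

Defaults follow the original training recipe: K = 4096, m = 0.99, t = 0.1,
Adam with learning rate 1e-4, augmentation by random horizontal flip and
rotation in [-20, 20] degrees followed by a 224-px center crop. The backbone
depth, network input size, queue size and epoch count are configurable; the
desk-scale profile used throughout the test suite is a 3-block conv net on
32-px inputs with K = 256, which trains in seconds on one CPU core.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .nn import Adam, ConvNet, softmax

__all__ = ["SSLConfig", "Encoder", "FeatureMatrix", "augment",
           "infonce_loss", "momentum_update", "train_elex",
           "extract_features", "preprocess_images"]


@dataclasses.dataclass
class SSLConfig:
    queue_size: int = 4096          # moco-k
    key_momentum: float = 0.99      # moco-m
    temperature: float = 0.1        # moco-t
    learning_rate: float = 1e-4
    rotation_range: float = 20.0    # degrees, +/-
    crop_size: int = 224
    feature_dim: int = 128
    backbone_channels: tuple = (16, 32, 64)
    input_size: int = 32            # network input after resize
    epochs: int = 10
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.queue_size < self.batch_size:
            raise ValueError("queue_size must be >= batch_size")
        if not 0.0 <= self.key_momentum <= 1.0:
            raise ValueError("key_momentum must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.feature_dim < 2:
            raise ValueError("feature_dim must be >= 2")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class Encoder:
    """Trained (or freshly initialised) tile feature extractor."""

    def __init__(self, net: ConvNet, config: SSLConfig, epochs_trained: int = 0,
                 loss_trajectory: list | None = None):
        self.net = net
        self.config = config
        self.epochs_trained = epochs_trained
        self.loss_trajectory = loss_trajectory or []
        self.provenance = {"config_hash": config.hash(), "epochs": epochs_trained}

    def embed(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """L2-normalized feature rows for uint8 images of shape (n, H, W, 3)."""
        x = preprocess_images(images, self.config.crop_size, self.config.input_size)
        out = []
        for i in range(0, len(x), batch_size):
            z, _ = self.net.forward(x[i:i + batch_size])
            out.append(z)
        z = np.concatenate(out) if out else np.empty((0, self.config.feature_dim))
        return _l2_normalize(z)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {"config": dataclasses.asdict(self.config),
                "epochs_trained": self.epochs_trained,
                "provenance": self.provenance}
        np.savez(path.with_suffix(".npz"),
                 **{f"p{i}": p for i, p in enumerate(self.net.params())})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "Encoder":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfgd = meta["config"]
        cfgd["backbone_channels"] = tuple(
            int(c) for c in str(cfgd["backbone_channels"]).strip("()").split(",") if c.strip()
        ) if isinstance(cfgd["backbone_channels"], str) else tuple(cfgd["backbone_channels"])
        cfg = SSLConfig(**cfgd)
        net = ConvNet(3, cfg.backbone_channels, cfg.feature_dim, cfg.input_size)
        with np.load(path.with_suffix(".npz")) as data:
            net.set_params([data[f"p{i}"] for i in range(len(data.files))])
        return cls(net, cfg, epochs_trained=meta["epochs_trained"])


@dataclasses.dataclass
class FeatureMatrix:
    """n_tiles x feature_dim embedding matrix aligned with a TileSet."""
    values: np.ndarray
    tile_keys: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2 or len(self.tile_keys) != self.values.shape[0]:
            raise ValueError("feature rows must align with tile keys")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_tiles(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# augmentation & preprocessing

def augment(tile_image: np.ndarray, seed: int, rotation_range: float = 20.0,
            crop_size: int = 224, return_params: bool = False):
    """Random flip + rotation in [-range, range] degrees + center crop.

    Deterministic given the seed. Raises if the input is smaller than the
    crop. With ``return_params`` also returns ``(flipped, angle)``.
    """
    img = np.asarray(tile_image)
    h, w = img.shape[:2]
    if h < crop_size or w < crop_size:
        raise ValueError(f"input {w}x{h} smaller than crop size {crop_size}")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    pil = Image.fromarray(img)
    flipped = bool(rng.random() < 0.5)
    if flipped:
        pil = pil.transpose(Image.FLIP_LEFT_RIGHT)
    angle = float(rng.uniform(-rotation_range, rotation_range))
    if rotation_range > 0:
        # corners uncovered by the rotation are filled with the mean colour;
        # with a 280->224 crop they are removed entirely, as in the original
        # recipe, but small tiles with no crop margin keep them
        fill = tuple(int(v) for v in np.asarray(pil).reshape(-1, 3).mean(axis=0))
        pil = pil.rotate(angle, resample=Image.BILINEAR, fillcolor=fill)
    left = (w - crop_size) // 2
    top = (h - crop_size) // 2
    pil = pil.crop((left, top, left + crop_size, top + crop_size))
    out = np.asarray(pil)
    return (out, (flipped, angle)) if return_params else out


def preprocess_images(images: np.ndarray, crop_size: int, input_size: int
                      ) -> np.ndarray:
    """Center crop, resize to the network input size, scale to [0,1], NCHW."""
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    n, h, w = images.shape[:3]
    cs = min(crop_size, h, w)
    top, left = (h - cs) // 2, (w - cs) // 2
    cropped = images[:, top:top + cs, left:left + cs]
    if cs != input_size:
        out = np.empty((n, input_size, input_size, 3), dtype=np.uint8)
        for i in range(n):
            out[i] = np.asarray(Image.fromarray(cropped[i]).resize(
                (input_size, input_size), Image.BILINEAR))
        cropped = out
    x = cropped.astype(np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# contrastive primitives

def _l2_normalize(z: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    return z / (np.linalg.norm(z, axis=-1, keepdims=True) + eps)


def _check_normalized(name: str, v: np.ndarray, tol: float = 1e-3) -> None:
    norms = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError(f"{name} must be L2-normalized (max |norm-1| = "
                         f"{np.abs(norms - 1.0).max():.2e})")


def infonce_loss(query: np.ndarray, positive_key: np.ndarray,
                 negative_queue: np.ndarray, temperature: float) -> float:
    """InfoNCE: -log( e^{q.k+/t} / (e^{q.k+/t} + sum_i e^{q.n_i/t}) ).

    Accepts a single embedding or a batch; returns the mean loss. All
    embeddings must be L2-normalized.
    """
    q = np.atleast_2d(np.asarray(query, dtype=np.float64))
    k = np.atleast_2d(np.asarray(positive_key, dtype=np.float64))
    neg = np.atleast_2d(np.asarray(negative_queue, dtype=np.float64))
    if neg.shape[0] < 1:
        raise ValueError("negative queue must hold at least one key")
    for name, v in (("query", q), ("positive_key", k), ("negative_queue", neg)):
        _check_normalized(name, v)
    l_pos = np.sum(q * k, axis=1, keepdims=True) / temperature
    l_neg = (q @ neg.T) / temperature
    logits = np.concatenate([l_pos, l_neg], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    losses = np.log(np.exp(logits).sum(axis=1)) - logits[:, 0]
    return float(losses.mean())


def _infonce_grad(q: np.ndarray, k: np.ndarray, neg: np.ndarray,
                  t: float) -> tuple:
    """Mean loss and its gradient with respect to the normalized queries."""
    l_pos = np.sum(q * k, axis=1, keepdims=True) / t
    l_neg = (q @ neg.T) / t
    logits = np.concatenate([l_pos, l_neg], axis=1)
    p = softmax(logits, axis=1)
    shifted = logits - logits.max(axis=1, keepdims=True)
    losses = np.log(np.exp(shifted).sum(axis=1)) - shifted[:, 0]
    b = q.shape[0]
    dq = ((p[:, :1] - 1.0) * k + p[:, 1:] @ neg) / (t * b)
    return float(losses.mean()), dq.astype(np.float32)


def momentum_update(key_params: Sequence[np.ndarray],
                    query_params: Sequence[np.ndarray], m: float) -> list:
    """theta_k <- m * theta_k + (1 - m) * theta_q, elementwise, in place."""
    if len(key_params) != len(query_params):
        raise ValueError("parameter lists differ in length")
    for pk, pq in zip(key_params, query_params):
        if pk.shape != pq.shape:
            raise ValueError(f"parameter shape mismatch {pk.shape} vs {pq.shape}")
        pk *= m
        pk += (1.0 - m) * pq
    return list(key_params)


# ---------------------------------------------------------------------------
# training & inference

def train_elex(tileset, config: SSLConfig):
    """Train the feature extractor on an (unlabeled) tile set.

    Returns an :class:`Encoder` whose ``loss_trajectory`` holds the mean
    InfoNCE loss per epoch. With ``epochs=0`` the randomly initialised
    encoder is returned as-is (usable for embedding).
    """
    images = tileset.images() if hasattr(tileset, "images") else np.asarray(tileset)
    n = len(images)
    if n < 2 * config.batch_size:
        raise ValueError(f"need at least {2 * config.batch_size} tiles, got {n}")
    rng = np.random.default_rng(config.seed)
    net_q = ConvNet(3, config.backbone_channels, config.feature_dim,
                    config.input_size, seed=int(rng.integers(2**31)))
    net_k = net_q.copy()
    opt = Adam(net_q.params(), lr=config.learning_rate)
    # queue starts as random unit vectors and is FIFO-replaced by real keys
    queue = _l2_normalize(rng.standard_normal(
        (config.queue_size, config.feature_dim))).astype(np.float32)
    q_ptr = 0
    trajectory = []
    cs, t = config.crop_size, config.temperature
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start:start + config.batch_size]
            seeds = rng.integers(2**31, size=(len(idx), 2))
            v_q = np.stack([augment(images[i], seeds[j, 0], config.rotation_range,
                                    min(cs, images[i].shape[0]))
                            for j, i in enumerate(idx)])
            v_k = np.stack([augment(images[i], seeds[j, 1], config.rotation_range,
                                    min(cs, images[i].shape[0]))
                            for j, i in enumerate(idx)])
            x_q = preprocess_images(v_q, cs, config.input_size)
            x_k = preprocess_images(v_k, cs, config.input_size)
            z_q_raw, cache = net_q.forward(x_q, train=True)
            z_k_raw, _ = net_k.forward(x_k)
            q = _l2_normalize(z_q_raw)
            k = _l2_normalize(z_k_raw)
            loss, dq = _infonce_grad(q, k, queue, t)
            # back through the L2 normalisation of the query
            norms = np.linalg.norm(z_q_raw, axis=1, keepdims=True) + 1e-12
            dz = (dq - np.sum(dq * q, axis=1, keepdims=True) * q) / norms
            grads = net_q.backward(dz.astype(np.float32), cache)
            opt.step(net_q.params(), grads)
            momentum_update(net_k.params(), net_q.params(), config.key_momentum)
            # FIFO enqueue of the new keys (oldest evicted first)
            b = k.shape[0]
            for row in k:
                queue[q_ptr] = row
                q_ptr = (q_ptr + 1) % config.queue_size
            epoch_losses.append(loss)
        trajectory.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
    return Encoder(net_q, config, epochs_trained=config.epochs,
                   loss_trajectory=trajectory)


def extract_features(encoder: Encoder, tileset, batch_size: int = 256
                     ) -> FeatureMatrix:
    """Embed every tile of a TileSet; row order matches the tile order."""
    images = tileset.images() if hasattr(tileset, "images") else np.asarray(tileset)
    keys = ([t.key for t in tileset] if hasattr(tileset, "tiles")
            else list(range(len(images))))
    if len(images) == 0:
        return FeatureMatrix(np.empty((0, encoder.config.feature_dim)), [])
    z = encoder.embed(images, batch_size=batch_size)
    return FeatureMatrix(z, keys)
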