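"""Minimal CPU convolutional network with manual backpropagation.

Supports the two model shapes used by the pipeline: a small conv backbone
with a linear projection head (the tile feature extractor) and the same
backbone with a softmax classification head (the finding classifier).
Everything is plain numpy; forward/backward passes are deterministic given
the seed used to initialise parameters and order batches.

Layout convention: images are arrays of shape (N, C, H, W), float32 in
[0, 1]. Convolutions are 3x3, stride 2, padding 1, each halving the spatial
size, followed by ReLU; a global average pool and a dense projection produce
the feature vector.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ConvNet", "Adam", "softmax", "he_init"]


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """Unfold (N,C,H,W) into (N*Ho*Wo, C*k*k) patches."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                      # N,C,Ho,Wo,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape: tuple, k: int, stride: int, pad: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += d6[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w]


class ConvNet:
    """Conv backbone + linear head.

    Parameters are a flat list of numpy arrays so the momentum update of a
    key encoder is a plain elementwise blend over ``params()``.
    """

    KERNEL = 3
    STRIDE = 2
    PAD = 1

    def __init__(self, in_channels: int = 3, channels: tuple = (16, 32, 64),
                 out_dim: int = 128, input_size: int = 32, seed: int = 0):
        self.in_channels = in_channels
        self.channels = tuple(channels)
        self.out_dim = out_dim
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        cin = in_channels
        for cout in self.channels:
            fan = cin * self.KERNEL ** 2
            self.W.append(he_init(rng, (cout, fan), fan))
            self.b.append(np.zeros(cout, dtype=np.float32))
            cin = cout
        # dense head on the globally pooled activations
        self.Wd = he_init(rng, (out_dim, cin), cin)
        self.bd = np.zeros(out_dim, dtype=np.float32)

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list:
        return [*self.W, *self.b, self.Wd, self.bd]

    def set_params(self, ps: list) -> None:
        nb = len(self.channels)
        self.W = [p.astype(np.float32) for p in ps[:nb]]
        self.b = [p.astype(np.float32) for p in ps[nb:2 * nb]]
        self.Wd = ps[2 * nb].astype(np.float32)
        self.bd = ps[2 * nb + 1].astype(np.float32)

    def copy(self) -> "ConvNet":
        other = ConvNet(self.in_channels, self.channels, self.out_dim,
                        self.input_size, seed=0)
        other.set_params([p.copy() for p in self.params()])
        return other

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False):
        """Return (out, cache). out has shape (N, out_dim)."""
        cache = {"cols": [], "shapes": [], "howo": [], "relu": []}
        a = x.astype(np.float32)
        for W, b in zip(self.W, self.b):
            cols, ho, wo = _im2col(a, self.KERNEL, self.STRIDE, self.PAD)
            z = cols @ W.T + b
            n = a.shape[0]
            z = z.reshape(n, ho, wo, W.shape[0]).transpose(0, 3, 1, 2)
            mask = z > 0
            if train:
                cache["cols"].append(cols)
                cache["shapes"].append(a.shape)
                cache["howo"].append((ho, wo))
                cache["relu"].append(mask)
            a = np.where(mask, z, 0.0)
        pooled = a.mean(axis=(2, 3))                         # N, C
        out = pooled @ self.Wd.T + self.bd
        if train:
            cache["pooled"] = pooled
            cache["pool_shape"] = a.shape
        return out, cache

    def backward(self, dout: np.ndarray, cache: dict) -> list:
        """Gradients in the order of params(); also returns nothing for dx."""
        gWd = dout.T @ cache["pooled"]
        gbd = dout.sum(axis=0)
        n, c, h, w = cache["pool_shape"]
        dpool = dout @ self.Wd                               # N, C
        da = np.broadcast_to(dpool[:, :, None, None] / (h * w),
                             (n, c, h, w)).astype(np.float32)
        gW = [None] * len(self.W)
        gb = [None] * len(self.W)
        for i in reversed(range(len(self.W))):
            mask = cache["relu"][i]
            dz = np.where(mask, da, 0.0)                     # N,Cout,Ho,Wo
            ho, wo = cache["howo"][i]
            cout = dz.shape[1]
            dzc = dz.transpose(0, 2, 3, 1).reshape(-1, cout)
            gW[i] = dzc.T @ cache["cols"][i]
            gb[i] = dzc.sum(axis=0)
            dcols = dzc @ self.W[i]
            da = _col2im(dcols, cache["shapes"][i], self.KERNEL,
                         self.STRIDE, self.PAD, ho, wo)
        return [*gW, *gb, gWd, gbd]


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adaptive moment estimation over a list of parameter arrays."""

    def __init__(self, params: list, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
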