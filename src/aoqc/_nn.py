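"""Minimal CNN building blocks on numpy.

Only what the compact patch classifier needs: same-padding convolution
(im2col + matmul, so the heavy lifting is BLAS), ReLU, 2x2 max-pooling,
dense layers, and softmax cross-entropy with optional per-class weights.
Everything is float32 and deterministic given the RNG passed to ``init``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "softmax",
    "cross_entropy",
]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) patch matrix with same-padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Conv2D:
    """k x k convolution, stride 1, same padding."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU nets
        self.W = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.W.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        dy_m = dy.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW = (dy_m.T @ cols).astype(np.float32)
        self.db = dy_m.sum(axis=0).astype(np.float32)
        # input gradient = convolution of dy with spatially-flipped weights
        Wt = (
            self.W.reshape(self.c_out, self.c_in, self.k, self.k)[:, :, ::-1, ::-1]
            .transpose(1, 0, 2, 3)
            .reshape(self.c_in, self.c_out * self.k * self.k)
        )
        dy_cols = _im2col(dy, self.k)
        dx = (dy_cols @ Wt.T).reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)
        return dx.astype(np.float32)

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    params: list = []


class MaxPool2:
    """2x2 max pooling, stride 2; trailing odd row/column dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._cache = (x.shape, xr, out)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (shape, xr, out) = self._cache
        mask = xr == out[:, :, :, None, :, None]
        # split gradient across ties so totals are conserved
        counts = mask.sum(axis=(3, 5), keepdims=True)
        grad = mask * (dy[:, :, :, None, :, None] / counts)
        n, c, h, w = shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(shape, dtype=np.float32)
        dx[:, :, : h2 * 2, : w2 * 2] = grad.reshape(n, c, h2 * 2, w2 * 2)
        return dx

    params: list = []


class Flatten:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    params: list = []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = (self._x.T @ dy).astype(np.float32)
        self.db = dy.sum(axis=0).astype(np.float32)
        return (dy @ self.W.T).astype(np.float32)

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(
    probs: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Mean weighted cross-entropy and its gradient w.r.t. the logits."""
    n = probs.shape[0]
    w = np.ones(n, dtype=np.float32) if sample_weight is None else sample_weight
    eps = 1e-12
    loss = float(-(w * np.log(probs[np.arange(n), y] + eps)).sum() / w.sum())
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    grad *= (w / w.sum())[:, None]
    return loss, grad.astype(np.float32)


class SGDMomentum:
    def __init__(self, layers, lr: float, momentum: float = 0.9):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self._vel = {}

    def step(self) -> None:
        for li, layer in enumerate(self.layers):
            for name, param, grad_attr in layer.params:
                g = getattr(layer, grad_attr)
                key = (li, name)
                v = self._vel.get(key)
                v = g if v is None else self.momentum * v + g
                self._vel[key] = v
                param -= self.lr * v
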