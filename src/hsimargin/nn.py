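"""Minimal NumPy neural-network core: conv/dense layers with manual
backpropagation and an Adam optimizer.

Only what the dual-branch pixel classifier needs is implemented: valid
(unpadded) strided 2-D and 1-D convolutions via im2col, ReLU, global
average pooling, dense layers, inverted dropout, and numerically stable
binary cross-entropy with logits. Everything is float32 and fully
deterministic given the seeding ``Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D", "Conv1D", "Dense", "ReLU", "GlobalAvgPool", "Dropout",
    "Sequential", "Adam", "bce_with_logits", "sigmoid", "he_init",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(
    logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Mean weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    w = np.where(y > 0.5, pos_weight, 1.0)
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(w * per))
    grad = (w * (sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: holds ``params`` and matching ``grads`` lists."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid strided 2-D convolution on (N, H, W, C) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k, self.s, self.c_in, self.c_out = kernel, stride, c_in, c_out
        w = he_init(rng, (c_in * kernel * kernel, c_out), c_in * kernel * kernel)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, s = self.k, self.s
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        win = win[:, ::s, ::s]  # (N, Ho, Wo, C, k, k)
        return win

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        win = self._im2col(x)
        n, ho, wo = win.shape[:3]
        # column order (k, k, C) to match weight layout
        col = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
            n * ho * wo, -1
        )
        self._col, self._out_hw = col, (ho, wo)
        w, b = self.params
        return (col @ w + b).reshape(n, ho, wo, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, ho, wo, _ = dy.shape
        dflat = dy.reshape(n * ho * wo, self.c_out)
        w, _ = self.params
        self.grads[0][...] = self._col.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcol = (dflat @ w.T).reshape(n, ho, wo, self.k, self.k, self.c_in)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        s = self.s
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i : i + ho * s : s, j : j + wo * s : s, :] += dcol[:, :, :, i, j, :]
        return dx


class Conv1D(Layer):
    """Valid strided 1-D convolution on (N, L, C) input."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.k, self.s, self.c_in, self.c_out = kernel, stride, c_in, c_out
        w = he_init(rng, (c_in * kernel, c_out), c_in * kernel)
        b = np.zeros(c_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        win = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)[:, :: self.s]
        n, lo = win.shape[:2]  # win: (N, Lo, C, k)
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(n * lo, -1)
        self._col, self._lo = col, lo
        w, b = self.params
        return (col @ w + b).reshape(n, lo, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, lo, _ = dy.shape
        dflat = dy.reshape(n * lo, self.c_out)
        w, _ = self.params
        self.grads[0][...] = self._col.T @ dflat
        self.grads[1][...] = dflat.sum(axis=0)
        dcol = (dflat @ w.T).reshape(n, lo, self.k, self.c_in)
        dx = np.zeros(self._x_shape, dtype=np.float32)
        for i in range(self.k):
            dx[:, i : i + lo * self.s : self.s, :] += dcol[:, :, i, :]
        return dx


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        w = he_init(rng, (d_in, d_out), d_in)
        b = np.zeros(d_out, dtype=np.float32)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ w.T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class GlobalAvgPool(Layer):
    """Mean over all axes between batch and channel."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        axes = tuple(range(1, x.ndim - 1))
        self._count = int(np.prod([x.shape[a] for a in axes]))
        return x.mean(axis=axes)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = (self._shape[0],) + (1,) * (len(self._shape) - 2) + (self._shape[-1],)
        return np.broadcast_to(
            dy.reshape(shape) / self._count, self._shape
        ).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity at rate 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self._rng = rate, rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    @property
    def all_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def all_grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the standard bias correction (beta1 0.9, beta2 0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
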