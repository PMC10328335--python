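"""Layers, losses and the Adam optimiser.

Shapes follow the NCHW convention. Convolutions are stride-1 with "same"
zero padding (odd kernels only); the im2col views feed BLAS matmuls via
einsum so training a few tiny networks stays inside a CPU test budget.
All parameters are float64 for reproducibility across platforms.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "GlobalMaxPool",
    "Upsample2x",
    "Flatten",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
    "mse_loss",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: stateless unless it owns parameters."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3-style same-padding convolution, stride 1, He initialisation."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, *, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported")
        self.k = kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        b = np.zeros(c_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        w, b = self.params
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self._cols = cols
        out = np.einsum("nchwij,ocij->nohw", cols, w, optimize=True)
        return out + b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        cols = self._cols
        self.grads[0] += np.einsum("nchwij,nohw->ocij", cols, dy, optimize=True)
        self.grads[1] += dy.sum(axis=(0, 2, 3))
        p = self.pad
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        dy_cols = sliding_window_view(dyp, (self.k, self.k), axis=(2, 3))
        w_rot = w[:, :, ::-1, ::-1]
        return np.einsum("nohwij,ocij->nchw", dy_cols, w_rot, optimize=True)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        b = np.zeros(d_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.params[0].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    """2x2 max pooling; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        expanded = self._mask * dy[:, :, :, None, :, None]
        # ties (rare with float activations) split gradient; normalise by count
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        expanded = expanded / counts
        return expanded.reshape(self._shape)


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sum-pools 2x2 blocks."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalMaxPool(Layer):
    """Spatial max over each channel: (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        n, c, h, w = x.shape
        flat = x.reshape(n, c, h * w)
        self._arg = flat.argmax(axis=2)
        return flat.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        dx = np.zeros((n, c, h * w))
        ii, jj = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        dx[ii, jj, self._arg] = dy
        return dx.reshape(self._x_shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g[...] = 0.0

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state, strict=True):
            p[...] = s

    def clone_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.state_dict())


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in model.parameters()]
        self.v = [np.zeros_like(p) for p in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.model.parameters(), self.model.gradients(),
                              self.m, self.v, strict=True):
            m[...] = self.b1 * m + (1.0 - self.b1) * g
            v[...] = self.b2 * v + (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    # log(1+exp(-|x|)) + max(x,0) - x*t  is the stable elementwise form
    loss = np.mean(np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0.0)
                   - logits * targets)
    grad = (sigmoid(logits) - targets) / logits.size
    return float(loss), grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error averaged over every output coordinate."""
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size
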