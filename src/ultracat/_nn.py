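"""Minimal NumPy CNN engine: layers, losses, momentum SGD.

Only what the VGG-style backbones need: 3x3 same-padding convolution, ReLU,
2x2 max pooling, adaptive average pooling to a fixed spatial side, flatten,
fully connected layers, binary cross-entropy with logits, softmax
cross-entropy, and stochastic gradient descent with momentum (velocity
``v ← μ v + g``, update ``w ← w − η v``).

Tensors are ``float32`` in NCHW layout.  Each layer caches what its backward
pass needs only when ``train=True``; inference allocates nothing persistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "AdaptiveAvgPool2d",
    "Flatten",
    "Linear",
    "SGD",
    "bce_with_logits",
    "softmax_cross_entropy",
    "sigmoid",
    "softmax",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray | None = None
    trainable: bool = True
    name: str = ""

    def zero_grad(self) -> None:
        self.grad = None

    def add_grad(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Layer):
    """3x3 cross-correlation, stride 1, zero padding 1 (spatial size preserved)."""

    KSIZE = 3

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator, name: str = ""):
        self.in_channels = in_channels
        self.out_channels = out_channels
        k = self.KSIZE
        self.W = Param(he_init(rng, (out_channels, in_channels, k, k), in_channels * k * k),
                       name=f"{name}.W")
        self.b = Param(np.zeros(out_channels, dtype=np.float32), name=f"{name}.b")
        self._x_windows: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    @staticmethod
    def _windows(x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        return sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        w = self._windows(x)
        if train:
            self._x_windows = w
        out = np.einsum("ockl,nchwkl->nohw", self.W.value, w, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w = self._x_windows
        self.W.add_grad(np.einsum("nohw,nchwkl->ockl", grad, w, optimize=True))
        self.b.add_grad(grad.sum(axis=(0, 2, 3)))
        gw = self._windows(grad)
        Wf = self.W.value[:, :, ::-1, ::-1]
        dx = np.einsum("ockl,nohwkl->nchw", Wf, gw, optimize=True)
        self._x_windows = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0)
        return np.maximum(x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @staticmethod
    def _tiles(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial dims, got {h}x{w}")
        return (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        t = self._tiles(x)
        if train:
            self._argmax = t.argmax(axis=-1)
            self._shape = x.shape
        return t.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        t = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(t, self._argmax[..., None], grad[..., None], axis=-1)
        out = (
            t.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        self._argmax = None
        self._shape = None
        return out


class AdaptiveAvgPool2d(Layer):
    """Average pooling onto a fixed ``side x side`` grid for any input size.

    Bin i spans input rows [floor(i*H/side), ceil((i+1)*H/side)); this keeps
    the classifier's input spatial size constant regardless of how many
    pooling stages survive upstream, which is what makes depth pruning
    possible without touching the fully connected architecture.
    """

    def __init__(self, side: int):
        self.side = side
        self._in_shape: tuple[int, ...] | None = None

    def _bins(self, n: int) -> list[tuple[int, int]]:
        s = self.side
        return [(int(np.floor(i * n / s)), max(int(np.ceil((i + 1) * n / s)), int(np.floor(i * n / s)) + 1)) for i in range(s)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._in_shape = x.shape
        rows, cols = self._bins(h), self._bins(w)
        out = np.empty((n, c, self.side, self.side), dtype=x.dtype)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                out[:, :, i, j] = x[:, :, r0:r1, c0:c1].mean(axis=(2, 3))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        rows, cols = self._bins(h), self._bins(w)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        for i, (r0, r1) in enumerate(rows):
            for j, (c0, c1) in enumerate(cols):
                area = (r1 - r0) * (c1 - c0)
                dx[:, :, r0:r1, c0:c1] += grad[:, :, i, j][:, :, None, None] / area
        self._in_shape = None
        return dx


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad.reshape(self._shape)
        self._shape = None
        return out


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, name: str = ""):
        self.in_features = in_features
        self.out_features = out_features
        self.W = Param(he_init(rng, (out_features, in_features), in_features), name=f"{name}.W")
        self.b = Param(np.zeros(out_features, dtype=np.float32), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.add_grad(grad.T @ self._x)
        self.b.add_grad(grad.sum(axis=0))
        dx = grad @ self.W.value
        self._x = None
        return dx


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p in self.params:
            if not p.trainable or p.grad is None:
                continue
            v = self._velocity.get(id(p))
            v = p.grad if v is None else self.momentum * v + p.grad
            self._velocity[id(p)] = v
            p.value -= (self.lr * v).astype(p.value.dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores; returns (loss, dloss/dlogits)."""
    z = logits.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy with integer class targets."""
    p = softmax(logits.astype(np.float64), axis=1)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
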