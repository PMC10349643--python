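"""Minimal NumPy CNN engine used by the localization and segmentation networks.

Implements exactly the layers the two networks need — same-padded 3x3
convolutions (optionally strided), ReLU, 2x2 max pooling, nearest-neighbour
2x upsampling, channel concatenation, global average pooling and a linear
head — with explicit forward/backward passes and an Adam optimizer.
Everything runs in float32 on (N, C, H, W) arrays; all randomness flows
through a caller-supplied :class:`numpy.random.Generator`, so training is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "glorot_uniform",
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "Upsample2x",
    "GlobalAvgPool",
    "Linear",
    "Adam",
    "softmax_channels",
    "softmax_logits",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, fan_out: int) -> np.ndarray:
    limit = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d:
    """Same-padded kxk convolution via im2col + BLAS matmul.

    With stride s the output is ceil(H/s) x ceil(W/s) for same padding,
    assuming H, W divisible by s (the networks guarantee this by padding
    inputs to a multiple of their total downsampling factor).
    """

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int,
                 ksize: int = 3, stride: int = 1, name: str = "conv") -> None:
        fan_in = in_ch * ksize * ksize
        fan_out = out_ch * ksize * ksize
        self.W = Param(glorot_uniform(rng, (out_ch, in_ch, ksize, ksize),
                                      fan_in, fan_out), name + ".W")
        self.b = Param(np.zeros(out_ch, dtype=np.float32), name + ".b")
        self.ksize = ksize
        self.stride = stride
        self.pad = ksize // 2
        self._cache: tuple | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
        n, c, h, w = x.shape
        p, k, s = self.pad, self.ksize, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        # (N, C, ho, wo, k, k) -> (C*k*k, N*ho*wo)
        col = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * k * k, n * ho * wo)
        return np.ascontiguousarray(col), (n, c, h, w, ho, wo)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        col, dims = self._im2col(x)
        n, c, h, w, ho, wo = dims
        oc = self.W.value.shape[0]
        wmat = self.W.value.reshape(oc, -1)
        y = wmat @ col + self.b.value[:, None]
        y = y.reshape(oc, n, ho, wo).transpose(1, 0, 2, 3)
        if train:
            self._cache = (col, dims)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, (n, c, h, w, ho, wo) = self._cache
        self._cache = None
        oc = dy.shape[1]
        dyf = dy.transpose(1, 0, 2, 3).reshape(oc, -1)
        self.W.grad += (dyf @ col.T).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=1)
        wmat = self.W.value.reshape(oc, -1)
        dcol = wmat.T @ dyf  # (C*k*k, N*ho*wo)
        k, p, s = self.ksize, self.pad, self.stride
        dcol = dcol.reshape(c, k, k, n, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcol[:, i, j].transpose(1, 0, 2, 3)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class ReLU:
    params: list[Param] = []

    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0.0)
        self._mask = None
        return dx


class MaxPool2x2:
    params: list[Param] = []

    def __init__(self) -> None:
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._cache = (x.shape, xr == y[:, :, :, None, :, None])
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape, mask = self._cache
        self._cache = None
        n, c, h, w = shape
        dxr = mask * dy[:, :, :, None, :, None]
        return dxr.reshape(n, c, h, w).astype(np.float32, copy=False)


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    params: list[Param] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool:
    params: list[Param] = []

    def __init__(self) -> None:
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        scale = np.float32(1.0 / (h * w))
        return np.broadcast_to((dy * scale)[:, :, None, None],
                               dy.shape + (h, w)).astype(np.float32)


class Linear:
    def __init__(self, rng: np.random.Generator, in_dim: int, out_dim: int,
                 name: str = "fc") -> None:
        self.W = Param(glorot_uniform(rng, (out_dim, in_dim), in_dim, out_dim),
                       name + ".W")
        self.b = Param(np.zeros(out_dim, dtype=np.float32), name + ".b")
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.W.value
        self._x = None
        return dx


class Adam:
    """Adam with optional L2 weight decay added to the raw gradient."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Softmax over axis 1 of an (N, K, H, W) logit array."""
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=1, keepdims=True)


def softmax_logits(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax of an (N, K) logit array."""
    zs = z - z.max(axis=1, keepdims=True)
    e = np.exp(zs)
    return e / e.sum(axis=1, keepdims=True)
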