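"""Minimal float32 neural-network layers with explicit backpropagation.

The package trains two small convolutional networks (a patch classifier and
a U-Net-style refiner) on a single CPU.  This module provides just the
layers those models need, in NHWC layout, with deterministic seeded
initialisation and an Adam optimiser supporting gradient accumulation.

Conventions
-----------
- All activations and parameters are float32.
- ``forward(x, train=..., rng=...)`` caches what ``backward`` needs;
  a layer is used for one forward/backward pair at a time.
- Parameter gradients ACCUMULATE across backward calls until
  ``zero_grad``; this is what makes gradient accumulation exact.
- Max-pool ties propagate gradient to every tied input; the rule is
  deterministic, which is what batch-equivalence tests require.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 (or kxk) same-padding, stride-1 convolution."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (k * k * cin))
        self.k = k
        self.w = Param(rng.standard_normal((k, k, cin, cout)) * scale)
        self.b = Param(np.zeros(cout))
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        k = self.k
        p = k // 2
        b_, h, w_, cin = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._xp = xp
        cout = self.w.value.shape[-1]
        y = np.broadcast_to(self.b.value, (b_, h, w_, cout)).copy()
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di : di + h, dj : dj + w_, :]
                y += (xs.reshape(-1, cin) @ self.w.value[di, dj]).reshape(
                    b_, h, w_, cout
                )
        return y

    def backward(self, dy):
        k = self.k
        p = k // 2
        xp = self._xp
        b_, hp, wp, cin = xp.shape
        h, w_ = hp - 2 * p, wp - 2 * p
        cout = dy.shape[-1]
        dy2 = dy.reshape(-1, cout)
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, di : di + h, dj : dj + w_, :].reshape(-1, cin)
                self.w.grad[di, dj] += xs.T @ dy2
                dxp[:, di : di + h, dj : dj + w_, :] += (
                    dy2 @ self.w.value[di, dj].T
                ).reshape(b_, h, w_, cin)
        self.b.grad += dy2.sum(axis=0)
        self._xp = None
        if p:
            return dxp[:, p:-p, p:-p, :]
        return dxp


class BatchNorm(Layer):
    """Batch normalisation over all non-channel axes (2D or 4D input)."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.run_mean = np.zeros(c, dtype=F32)
        self.run_var = np.ones(c, dtype=F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False, rng=None):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (
                self.momentum * self.run_mean + (1 - self.momentum) * mean
            ).astype(F32)
            self.run_var = (
                self.momentum * self.run_var + (1 - self.momentum) * var
            ).astype(F32)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv.astype(F32), axes, train, x.shape)
        return (xhat * self.gamma.value + self.beta.value).astype(F32)

    def backward(self, dy):
        xhat, inv, axes, train, shape = self._cache
        self._cache = None
        n = np.prod([shape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = dy * self.gamma.value
        if not train:
            return (g * inv).astype(F32)
        dxhat_sum = g.sum(axis=axes)
        dxhat_xhat = (g * xhat).sum(axis=axes)
        dx = inv / n * (n * g - dxhat_sum - xhat * dxhat_xhat)
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        m = self._mask
        self._mask = None
        return dy * m


class Dropout(Layer):
    def __init__(self, p: float):
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(F32) / F32(keep)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        m = self._mask
        self._mask = None
        return dy * m


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; gradient goes to every tied maximum."""

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        self._mask = xr == y[:, :, None, :, None, :]
        self._shape = x.shape
        return y

    def backward(self, dy):
        b, h, w, c = self._shape
        dyr = np.broadcast_to(
            dy[:, :, None, :, None, :], (b, h // 2, 2, w // 2, 2, c)
        )
        dx = (dyr * self._mask).reshape(b, h, w, c).astype(F32)
        self._mask = None
        return dx


class AvgPoolN(Layer):
    """Non-overlapping n x n mean pooling (used as a cheap downscale)."""

    def __init__(self, n: int):
        self.n = n

    def forward(self, x, train=False, rng=None):
        n = self.n
        b, h, w, c = x.shape
        self._shape = x.shape
        return x.reshape(b, h // n, n, w // n, n, c).mean(axis=(2, 4))

    def backward(self, dy):
        n = self.n
        b, h, w, c = self._shape
        dx = np.broadcast_to(
            dy[:, :, None, :, None, :] / F32(n * n), (b, h // n, n, w // n, n, c)
        )
        return dx.reshape(b, h, w, c).astype(F32)


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        b, h, w, c = self._shape
        return np.broadcast_to(
            dy[:, None, None, :] / F32(h * w), (b, h, w, c)
        ).astype(F32)


class UpsampleNearest2(Layer):
    def forward(self, x, train=False, rng=None):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(F32)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin))
        self.b = Param(np.zeros(nout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        x = self._x
        self._x = None
        self.w.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False, rng=None):
        for l in self.layers:
            x = l.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient through softmax given dL/dp and p = softmax(z)."""
    return (p * (dp - (dp * p).sum(axis=-1, keepdims=True))).astype(F32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s
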