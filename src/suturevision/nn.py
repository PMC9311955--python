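"""A compact numpy neural-network core with manual backpropagation.

Layers cache their forward inputs and implement an exact ``backward``
returning the gradient with respect to their input while accumulating
parameter gradients. That is all a residual classifier, its training loop
and gradient-based attribution (Grad-CAM) need, and it keeps every gradient
inspectable — the identity term that residual shortcuts add to the backward
pass can be read off directly.

Conventions: activations are ``(N, C, H, W)`` float64; convolution is
implemented as im2col + matmul; parameters are He-initialized from a seeded
generator.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Sequential",
    "softmax",
    "cross_entropy",
]


class Param:
    """A trainable tensor with its gradient accumulator.

    ``decay`` marks whether weight decay applies (True for conv/linear
    weights, False for biases and batch-norm scales/shifts).
    """

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, Ho, Wo, C, kh, kw) view-then-copy."""
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (N, C, Ho*, Wo*, kh, kw)
    v = v[:, :, ::stride, ::stride]
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))


class Conv2d(Layer):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel))
        self.w = Param(w, decay=True, name="conv_w")
        self.b = Param(np.zeros(c_out), decay=False, name="conv_b") if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.c_in, self.c_out = c_in, c_out

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, k, s)  # (N, Ho, Wo, C, k, k)
        self._cache = (x.shape, xp.shape, cols)
        n_, ho, wo = cols.shape[:3]
        flat = cols.reshape(n_ * ho * wo, c * k * k)
        wm = self.w.value.reshape(self.c_out, c * k * k)
        y = flat @ wm.T
        if self.b is not None:
            y += self.b.value
        return y.reshape(n_, ho, wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, xp_shape, cols = self._cache
        n, c, h, w = x_shape
        k, s, p = self.kernel, self.stride, self.pad
        n_, ho, wo = cols.shape[:3]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n_ * ho * wo, self.c_out)
        flat = cols.reshape(n_ * ho * wo, c * k * k)
        self.w.grad += (dyf.T @ flat).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.w.value.reshape(self.c_out, c * k * k)).reshape(
            n_, ho, wo, c, k, k
        )
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        if p:
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c), decay=False, name="bn_gamma")
        self.beta = Param(np.zeros(c), decay=False, name="bn_beta")
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        xhat = (x - m) / np.sqrt(v + self.eps)
        self._cache = (xhat, var)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, var = self._cache
        n, c, h, w = dy.shape
        m = n * h * w
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        inv_std = 1.0 / np.sqrt(var + self.eps)[None, :, None, None]
        dxhat = dy * g
        if self.train_mode:
            return (
                inv_std
                / m
                * (
                    m * dxhat
                    - dxhat.sum(axis=(0, 2, 3), keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                )
            )
        return dxhat * inv_std


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            if p
            else x
        )
        cols = _im2col(xp, k, k, s)  # (N, Ho, Wo, C, k, k)
        n, ho, wo, c = cols.shape[:4]
        flat = cols.reshape(n, ho, wo, c, k * k)
        self._arg = flat.argmax(axis=-1)
        self._shapes = (x.shape, xp.shape, (n, ho, wo, c))
        return flat.max(axis=-1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        x_shape, xp_shape, (n, ho, wo, c) = self._shapes
        dxp = np.zeros(xp_shape)
        ki, kj = np.divmod(self._arg, k)  # (N, Ho, Wo, C)
        nn, hh, ww, cc = np.meshgrid(
            np.arange(n), np.arange(ho), np.arange(wo), np.arange(c), indexing="ij"
        )
        rows = hh * s + ki
        cols_ = ww * s + kj
        np.add.at(dxp, (nn, cc, rows, cols_), dy.transpose(0, 2, 3, 1))
        if p:
            h, w = x_shape[2], x_shape[3]
            return dxp[:, :, p : p + h, p : p + w]
        return dxp


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean; absorbs any spatial size."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dy[:, :, None, None], self._shape) / (h * w)


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(
            rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in)), decay=True, name="fc_w"
        )
        self.b = Param(np.zeros(c_out), decay=False, name="fc_b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def set_train(self, mode: bool) -> None:
        self.train_mode = mode
        for l in self.layers:
            l.set_train(mode)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    loss = float(-np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n
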