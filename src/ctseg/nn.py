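"""A compact CPU neural-network engine for the segmentation backbones.

Layers keep explicit forward caches and hand-written backward passes; an
ADAM optimiser updates the parameters.  Convolutions are dimension-agnostic
(2D and 3D share one tap-loop implementation running on BLAS tensordots),
support dilation, and use "same" padding so the spatial shape is preserved
— the property the mixed-scale dense architecture relies on.

This is deliberately minimal: stride-1 odd kernels, 2x in-plane max pooling
and nearest upsampling are all the segmentation models here need.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Conv",
    "InstanceNorm",
    "LeakyReLU",
    "MaxPool2x2",
    "Upsample2x",
    "Adam",
    "softmax",
    "softmax_backward",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv(Layer):
    """Stride-1 "same" convolution over the trailing spatial axes.

    Input layout is (N, C, *spatial) with ``spatial_dims`` trailing axes
    (2 or 3).  Odd kernel size; dilation enlarges the receptive field
    without changing the output shape.  He-style initialisation.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        spatial_dims: int,
        ksize: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        if ksize % 2 != 1:
            raise ValueError("kernel size must be odd")
        if dilation < 1:
            raise ValueError("dilation must be >= 1")
        rng = rng or np.random.default_rng()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.dims, self.k, self.dilation = spatial_dims, ksize, dilation
        fan_in = in_ch * ksize**spatial_dims
        w = rng.standard_normal((out_ch, in_ch) + (ksize,) * spatial_dims)
        self.W = Param(w * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(out_ch))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _taps(self, spatial):
        d = self.dilation
        for tap in product(range(self.k), repeat=self.dims):
            yield tap, tuple(slice(t * d, t * d + s) for t, s in zip(tap, spatial))

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 + self.dims or x.shape[1] != self.in_ch:
            raise ValueError(f"expected (N, {self.in_ch}, *spatial^{self.dims}), got {x.shape}")
        p = self.dilation * (self.k // 2)
        pad = ((0, 0), (0, 0)) + ((p, p),) * self.dims
        xp = np.pad(x, pad)
        spatial = x.shape[2:]
        acc = np.zeros((x.shape[0],) + spatial + (self.out_ch,))
        for tap, sl in self._taps(spatial):
            xs = xp[(slice(None), slice(None)) + sl]
            acc += np.tensordot(xs, self.W.value[(slice(None), slice(None)) + tap], axes=([1], [1]))
        self._xp, self._spatial = xp, spatial
        y = np.moveaxis(acc, -1, 1)
        y += self.b.value.reshape((1, -1) + (1,) * self.dims)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, spatial = self._xp, self._spatial
        sum_axes = (0,) + tuple(range(2, 2 + self.dims))
        self.b.grad += dy.sum(axis=sum_axes)
        dxp = np.zeros_like(xp)
        for tap, sl in self._taps(spatial):
            idx = (slice(None), slice(None)) + sl
            xs = xp[idx]
            self.W.grad[(slice(None), slice(None)) + tap] += np.tensordot(
                dy, xs, axes=(sum_axes, sum_axes)
            )
            dxs = np.tensordot(dy, self.W.value[(slice(None), slice(None)) + tap], axes=([1], [0]))
            dxp[idx] += np.moveaxis(dxs, -1, 1)
        p = self.dilation * (self.k // 2)
        core = (slice(None), slice(None)) + tuple(slice(p, p + s) for s in spatial)
        del self._xp
        return dxp[core]


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation with a learnable affine.

    Suits batch size 1 (3D training) where batch statistics are undefined.
    """

    def __init__(self, ch: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = tuple(range(2, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv, self._axes = xhat, inv, axes
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes = self._xhat, self._inv, self._axes
        red = (0,) + axes
        self.gamma.grad += np.sum(dy * xhat, axis=red)
        self.beta.grad += np.sum(dy, axis=red)
        shape = (1, -1) + (1,) * (dy.ndim - 2)
        dxhat = dy * self.gamma.value.reshape(shape)
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * np.mean(dxhat * xhat, axis=axes, keepdims=True)
        ) * inv
        del self._xhat, self._inv
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 1e-2):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class MaxPool2x2(Layer):
    """2x2 max pooling over the last two (in-plane) axes.

    Works for both (N, C, H, W) and (N, C, D, H, W); the slice axis of 3D
    inputs is never pooled — CT volumes are anisotropic and short along it.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        *lead, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"in-plane size {h}x{w} not divisible by 2")
        xr = x.reshape(*lead, h // 2, 2, w // 2, 2)
        xr = np.moveaxis(xr, -3, -2).reshape(*lead, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        *lead, h, w = self._shape
        dxr = np.zeros(tuple(lead) + (h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._arg[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(*lead, h // 2, w // 2, 2, 2)
        dxr = np.moveaxis(dxr, -2, -3).reshape(*lead, h, w)
        return dxr


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling over the last two axes."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=-2).repeat(2, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        *lead, h, w = dy.shape
        return dy.reshape(*lead, h // 2, 2, w // 2, 2).sum(axis=(-3, -1))


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    """Map dL/dp to dL/dlogits for p = softmax(logits)."""
    inner = np.sum(dprobs * probs, axis=axis, keepdims=True)
    return probs * (dprobs - inner)


class Adam:
    """ADAM with the originally proposed configuration (lr 1e-3, 0.9/0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * np.square(p.grad)
            p.value -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
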