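"""Minimal numpy neural-network layers with explicit backward passes.

Only what the segmentation network needs: 2-D convolution and transpose
convolution (im2col/col2im based), batch normalization, SELU, channel-wise
spatial dropout, and an Adam optimizer.  Layers cache what their backward
pass needs on ``forward`` and accumulate parameter gradients in ``grads``.

All arrays are float64 NCHW.  Every backward pass is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "SELU",
    "Dropout2d",
    "Adam",
    "sigmoid",
]

# SELU constants (self-normalizing networks)
_SELU_ALPHA = 1.6732632423543772
_SELU_LAMBDA = 1.0507009873554805


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """Extract (k x k) patches at stride s from a padded NCHW array.

    Returns [B*ho*wo, C*k*k] with row order (b, row, col) and column order
    (channel, ki, kj).
    """
    b, c = xp.shape[:2]
    v = sliding_window_view(xp, (k, k), axis=(2, 3))  # [B,C,H',W',k,k]
    v = v[:, :, ::s, ::s][:, :, :ho, :wo]
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, c * k * k)
    return np.ascontiguousarray(cols)


def _col2im(
    cols: np.ndarray,
    b: int,
    c: int,
    hp: int,
    wp: int,
    k: int,
    s: int,
    ho: int,
    wo: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch columns back."""
    xp = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    ct = cols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for ki in range(k):
        for kj in range(k):
            xp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += ct[:, :, ki, kj]
    return xp


class Layer:
    """Base: parameter/gradient dicts plus forward/backward protocol."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, *, training=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding=1, rng=None):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be positive")
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p = kernel, stride, padding
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        # LeCun-normal init pairs with SELU activations
        self.params["w"] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (out_ch, fan_in))
        self.params["b"] = np.zeros(out_ch)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x, *, training=False, rng=None):
        b, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = _im2col(xp, k, s, ho, wo)
        y = cols @ self.params["w"].T + self.params["b"]
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(b, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        cols, (b, c, h, w), ho, wo = self._cache
        k, s, p = self.k, self.s, self.p
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)
        self.grads["w"] += dyf.T @ cols
        self.grads["b"] += dyf.sum(axis=0)
        dcols = dyf @ self.params["w"]
        dxp = _col2im(dcols, b, c, h + 2 * p, w + 2 * p, k, s, ho, wo)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; exact adjoint of Conv2d geometry."""

    def __init__(self, in_ch, out_ch, kernel=3, stride=1, padding=1,
                 output_padding=0, rng=None):
        super().__init__()
        if output_padding >= stride:
            raise ValueError("output_padding must be < stride")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.s, self.p, self.op = kernel, stride, padding, output_padding
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.params["w"] = rng.normal(
            0.0, 1.0 / np.sqrt(fan_in), (in_ch, out_ch * kernel * kernel)
        )
        self.params["b"] = np.zeros(out_ch)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def out_size(self, h: int) -> int:
        return (h - 1) * self.s + self.k - 2 * self.p + self.op

    def forward(self, x, *, training=False, rng=None):
        b, c, h, w = x.shape
        k, s, p = self.k, self.s, self.p
        ho, wo = self.out_size(h), self.out_size(w)
        xf = x.transpose(0, 2, 3, 1).reshape(-1, c)
        cols = xf @ self.params["w"]  # [B*H*W, out_ch*k*k]
        yp = _col2im(cols, b, self.out_ch, ho + 2 * p, wo + 2 * p, k, s, h, w)
        y = yp[:, :, p : p + ho, p : p + wo] if p else yp
        self._cache = (xf, x.shape, ho, wo)
        return y + self.params["b"][None, :, None, None]

    def backward(self, dy):
        xf, (b, c, h, w), ho, wo = self._cache
        k, s, p = self.k, self.s, self.p
        dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p))) if p else dy
        dcols = _im2col(dyp, k, s, h, w)  # [B*H*W, out_ch*k*k]
        self.grads["w"] += xf.T @ dcols
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dxf = dcols @ self.params["w"].T
        return dxf.reshape(b, h, w, c).transpose(0, 3, 1, 2)


class BatchNorm2d(Layer):
    def __init__(self, ch, momentum=0.1, eps=1e-5):
        super().__init__()
        self.ch, self.momentum, self.eps = ch, momentum, eps
        self.params["gamma"] = np.ones(ch)
        self.params["beta"] = np.zeros(ch)
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def forward(self, x, *, training=False, rng=None):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return (
            self.params["gamma"][None, :, None, None] * xhat
            + self.params["beta"][None, :, None, None]
        )

    def backward(self, dy):
        xhat, inv, training, shape = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += dy.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None] * inv[None, :, None, None]
        if not training:
            return dy * g
        n = shape[0] * shape[2] * shape[3]
        dxhat = dy * self.params["gamma"][None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class SELU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._neg = x < 0
        self._expx = np.exp(np.minimum(x, 0.0))
        return _SELU_LAMBDA * np.where(
            self._neg, _SELU_ALPHA * (self._expx - 1.0), x
        )

    def backward(self, dy):
        deriv = np.where(self._neg, _SELU_ALPHA * self._expx, 1.0)
        return dy * _SELU_LAMBDA * deriv


class Dropout2d(Layer):
    """Spatial (channel-wise) dropout; stochastic when asked, else identity."""

    def __init__(self, p=0.5):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, *, training=False, rng=None):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("active dropout requires an rng")
        keep = rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam over a list of (layer, param-name) pairs."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.entries = [
            (layer, name) for layer in layers for name in layer.params
        ]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(l.params[n]) for l, n in self.entries]
        self.v = [np.zeros_like(l.params[n]) for l, n in self.entries]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for layer, _ in self.entries:
            layer.zero_grad()
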