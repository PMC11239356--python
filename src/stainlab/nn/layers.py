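"""Minimal CPU conv-net layers with explicit backward passes.

Arrays are NCHW float64.  Each layer caches what its backward pass
needs on ``forward`` and accumulates parameter gradients on
``backward``; an optimizer consumes ``params()`` triples of
(name, value, gradient).  This is deliberately small: just the pieces a
Pix2Pix generator/discriminator pair needs, written for determinism and
exact testability (every layer is validated against finite differences
in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LeakyReLU",
    "ReLU",
    "ScaledTanh",
    "Sequential",
]


class Layer:
    train_mode: bool = True

    def params(self):
        return []

    def zero_grad(self) -> None:
        for _, _, g in self.params():
            g[...] = 0.0

    def set_mode(self, train: bool) -> None:
        self.train_mode = train

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N, C*k*k, oh*ow) patch matrix."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, k, k, oh, ow), dtype=xp.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow)


def _col2im(cols: np.ndarray, shape, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back onto (N, C, Hp, Wp)."""
    n, c, hp, wp = shape
    xp = np.zeros(shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, oh, ow)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    return xp


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel=4, stride=2, pad=1, rng=None, init_std=0.02):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        self.W = rng.normal(0.0, init_std, size=(out_ch, in_ch * kernel * kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        oh = (h + 2 * self.pad - self.k) // self.stride + 1
        ow = (w + 2 * self.pad - self.k) // self.stride + 1
        return oh, ow

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh, ow = self.out_size(h, w)
        if oh < 1 or ow < 1:
            raise ValueError(f"Conv2d: input {h}x{w} too small for kernel {self.k}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = _im2col(xp, self.k, self.stride, oh, ow)
        out = np.einsum("fk,nkl->nfl", self.W, cols, optimize=True)
        out += self.b[None, :, None]
        self._cache = (cols, x.shape, xp.shape, oh, ow)
        return out.reshape(n, self.out_ch, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, xpshape, oh, ow = self._cache
        n = xshape[0]
        dflat = dout.reshape(n, self.out_ch, oh * ow)
        self.dW += np.einsum("nfl,nkl->fk", dflat, cols, optimize=True)
        self.db += dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfl->nkl", self.W, dflat, optimize=True)
        dxp = _col2im(dcols, xpshape, self.k, self.stride, oh, ow)
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp


class ConvTranspose2d(Layer):
    """Transposed convolution; output size = (H-1)*stride - 2*pad + k."""

    def __init__(self, in_ch, out_ch, kernel=4, stride=2, pad=1, rng=None, init_std=0.02):
        rng = rng or np.random.default_rng(0)
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = kernel, stride, pad
        self.W = rng.normal(0.0, init_std, size=(in_ch, out_ch * kernel * kernel))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        oh = (h - 1) * self.stride - 2 * self.pad + self.k
        ow = (w - 1) * self.stride - 2 * self.pad + self.k
        xf = x.reshape(n, c, h * w)
        cols = np.einsum("ck,ncl->nkl", self.W, xf, optimize=True)
        padded_shape = (n, self.out_ch, oh + 2 * self.pad, ow + 2 * self.pad)
        outp = _col2im(cols, padded_shape, self.k, self.stride, h, w)
        out = outp[:, :, self.pad : self.pad + oh, self.pad : self.pad + ow] if self.pad else outp
        out = out + self.b[None, :, None, None]
        self._cache = (xf, (h, w), padded_shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xf, (h, w), padded_shape = self._cache
        n = dout.shape[0]
        dp = np.pad(dout, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        dcols = _im2col(dp, self.k, self.stride, h, w)
        self.dW += np.einsum("ncl,nkl->ck", xf, dcols, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("ck,nkl->ncl", self.W, dcols, optimize=True)
        return dx.reshape(n, self.in_ch, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W).

    Normalization always uses the statistics of the batch at hand (the
    Pix2Pix convention, where inference also runs in batch-stats mode);
    running averages are tracked for introspection only.
    """

    def __init__(self, ch, eps=1e-5, momentum=0.1):
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        if self.train_mode:
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma += (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] / m * (m * dxhat - s1 - xhat * s2)


class LeakyReLU(Layer):
    def __init__(self, slope=0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class ScaledTanh(Layer):
    """y = scale * tanh(x); bounds the generator output to (-scale, scale)."""

    def __init__(self, scale=0.5):
        self.scale = scale
        self._t = None

    def forward(self, x):
        self._t = np.tanh(x)
        return self.scale * self._t

    def backward(self, dout):
        return dout * self.scale * (1.0 - self._t**2)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{n}", v, g) for n, v, g in layer.params())
        return out

    def set_mode(self, train):
        for layer in self.layers:
            layer.set_mode(train)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
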