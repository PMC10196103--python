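"""2D layers: convolution, pooling, resampling, activations, dense.

All spatial tensors are ``(N, C, H, W)`` float64.  Convolutions are
stride-1 with 'same' zero padding; downsampling is done by max-pooling or
strided subsampling, upsampling by nearest-neighbour or bilinear
interpolation (factor 2 per step).
"""

from __future__ import annotations

import numpy as np

from .core import Module, Param

__all__ = [
    "Conv2d",
    "Linear",
    "LeakyReLU",
    "MaxPool2",
    "Subsample",
    "UpsampleNearest2",
    "UpsampleBilinear",
    "GlobalAvgPool",
]


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """k x k stride-1 'same' convolution (k odd, typically 3 or 1)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.weight = Param(he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.bias = Param(np.zeros(c_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        self._xp, self._in_shape = xp, x.shape
        out = np.empty((n, self.c_out, h, w))
        out[...] = self.bias.value[None, :, None, None]
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, :, di : di + h, dj : dj + w]
                # (N,C,H,W) x (F,C) -> (N,H,W,F)
                out += np.tensordot(patch, self.weight.value[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, _, h, w = grad.shape
        p = self.k // 2
        xp = self._xp
        gxp = np.zeros_like(xp)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        for di in range(self.k):
            for dj in range(self.k):
                patch = xp[:, :, di : di + h, dj : dj + w]
                # dW[f,c] = sum_{n,i,j} grad[n,f,i,j] * patch[n,c,i,j]
                self.weight.grad[:, :, di, dj] += np.tensordot(grad, patch, axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, di : di + h, dj : dj + w] += np.tensordot(
                    grad, self.weight.value[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        if p:
            return gxp[:, :, p:-p, p:-p]
        return gxp


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = Param(he_init(rng, (n_in, n_out), n_in))
        self.bias = Param(np.zeros(n_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.alpha * grad)


class MaxPool2(Module):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        flat &= np.cumsum(flat, axis=-1) == 1
        self._mask = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._in_shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self._mask * grad[:, :, :, None, :, None]
        return g.reshape(self._in_shape)


class Subsample(Module):
    """Strided subsampling by ``factor`` (the 'nearest' way down a pyramid)."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        f = self.factor
        return x[:, :, ::f, ::f]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = np.zeros(self._in_shape)
        f = self.factor
        out[:, :, ::f, ::f] = grad
        return out


class UpsampleNearest2(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def _bilinear_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Interpolation matrix mapping length-n_in signals to length n_out."""
    a = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        t = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        a[i, lo_c] += 1.0 - t
        a[i, hi_c] += t
    return a


class UpsampleBilinear(Module):
    """Bilinear upsampling by an integer factor (half-pixel-centred sampling)."""

    _cache: dict[tuple[int, int], np.ndarray] = {}

    def __init__(self, factor: int = 2):
        self.factor = factor

    @classmethod
    def _matrix(cls, n_in: int, factor: int) -> np.ndarray:
        key = (n_in, factor)
        if key not in cls._cache:
            cls._cache[key] = _bilinear_matrix(n_in * factor, n_in)
        return cls._cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, _, h, w = x.shape
        ah = self._matrix(h, self.factor)
        aw = self._matrix(w, self.factor)
        self._ah, self._aw = ah, aw
        y = np.einsum("ph,nchw->ncpw", ah, x, optimize=True)
        return np.einsum("qw,ncpw->ncpq", aw, y, optimize=True)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.einsum("qw,ncpq->ncpw", self._aw, grad, optimize=True)
        return np.einsum("ph,ncpw->nchw", self._ah, g, optimize=True)


class GlobalAvgPool(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None], self._in_shape) / (h * w)
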