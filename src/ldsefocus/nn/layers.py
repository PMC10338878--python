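"""Elementary layers with hand-written forward and backward passes.

Conventions
-----------
* Activations are ``(N, C, H, W)`` float arrays (``(N, C)`` for the dense
  head); the dtype follows the input, so the same graph runs in float32
  for training and float64 for finite-difference gradient checks.
* ``forward(x, train=...)`` caches whatever the backward pass needs;
  ``backward(grad_out)`` accumulates parameter gradients into
  ``Parameter.grad`` and returns the gradient w.r.t. the layer input.
* Convolution is im2col + matmul so the heavy lifting lands in BLAS.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Tanh",
    "MaxPool2d",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    """Minimal layer base: parameter iteration and grad reset."""

    def parameters(self) -> Iterator[Parameter]:
        for attr in vars(self).values():
            if isinstance(attr, Parameter):
                yield attr
            elif isinstance(attr, Module):
                yield from attr.parameters()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.parameters()

    def buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        """Non-trainable state (batch-norm running moments)."""
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                for sub, arr in attr.buffers():
                    yield f"{name}.{sub}", arr
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        for sub, arr in item.buffers():
                            yield f"{name}.{i}.{sub}", arr

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """Unfold ``(N,C,H,W)`` into ``(N, OH*OW, C*k*k)`` patch rows."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, oh, ow, _, _ = windows.shape
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), (n, c, h, w, oh, ow)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch-row gradients back."""
    n, c, h, w, oh, ow = shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += d[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


class Conv2d(Module):
    """2-D convolution (cross-correlation), bias-free: batch-norm follows."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 name: str = "conv", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.weight = Parameter(f"{name}.weight", w.astype(dtype))
        self.in_ch, self.out_ch, self.kernel, self.stride, self.pad = in_ch, out_ch, kernel, stride, pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, shape = _im2col(x, self.kernel, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T.astype(cols.dtype)  # (N, OH*OW, out_ch)
        n, _, _, _, oh, ow = shape
        self._cache = (cols, shape) if train else None
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, oh, ow)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, shape = self._cache
        n, c, h, w, oh, ow = shape
        g = grad.reshape(n, self.out_ch, oh * ow).transpose(0, 2, 1)  # (N, OHOW, out)
        dw = np.einsum("npo,npk->ok", g, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.value.shape).astype(self.weight.grad.dtype)
        wmat = self.weight.value.reshape(self.out_ch, -1).astype(grad.dtype)
        dcols = g @ wmat  # (N, OHOW, C*k*k)
        return _col2im(dcols, shape, self.kernel, self.stride, self.pad)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running moments for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn", dtype=np.float32):
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def buffers(self):
        yield "running_mean", self.running_mean
        yield "running_var", self.running_var

    def _axes_view(self, x):
        # supports (N,C,H,W) and (N,C)
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes, bshape = self._axes_view(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // x.shape[1]
            self.running_mean += self.momentum * (mean.astype(np.float64) - self.running_mean)
            unbiased = var.astype(np.float64) * (m / max(m - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) * inv_std.reshape(bshape)
        out = self.gamma.value.reshape(bshape).astype(x.dtype) * xhat + self.beta.value.reshape(bshape).astype(x.dtype)
        self._cache = (xhat, inv_std, bshape, axes, train)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, bshape, axes, trained = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes).astype(self.gamma.grad.dtype)
        self.beta.grad += grad.sum(axis=axes).astype(self.beta.grad.dtype)
        gscaled = grad * self.gamma.value.reshape(bshape).astype(grad.dtype)
        if not trained:
            return gscaled * inv_std.reshape(bshape)
        m = grad.size // grad.shape[1]
        sum_g = gscaled.sum(axis=axes, keepdims=True)
        sum_gx = (gscaled * xhat).sum(axis=axes, keepdims=True)
        return (inv_std.reshape(bshape)) * (gscaled - sum_g / m - xhat * sum_gx / m)


class ReLU(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Tanh(Module):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._out = np.tanh(x)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * (1.0 - self._out**2)


class MaxPool2d(Module):
    """Max pooling; ties resolve to the first window element."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n_, c_, oh, ow, _, _ = win.shape
        flat = win.reshape(n, c, oh, ow, k * k)
        self._argmax = flat.argmax(axis=-1)
        self._shape = (n, c, h, w, oh, ow)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w, oh, ow = self._shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        iy, ix = np.divmod(self._argmax, k)
        gy = np.arange(oh)[:, None] * s
        gx = np.arange(ow)[None, :] * s
        rows = gy[None, None] + iy
        colsx = gx[None, None] + ix
        nn, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        np.add.at(dxp, (nn[:, :, None, None], cc[:, :, None, None], rows, colsx), grad)
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class AvgPool2d(Module):
    """Non-overlapping average pooling; trailing odd rows/cols truncated."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k = self.kernel
        n, c, h, w = x.shape
        oh, ow = h // k, w // k
        self._in_shape = (n, c, h, w)
        v = x[:, :, : oh * k, : ow * k].reshape(n, c, oh, k, ow, k)
        return v.mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel
        n, c, h, w = self._in_shape
        oh, ow = grad.shape[2], grad.shape[3]
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        expanded = np.repeat(np.repeat(grad, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, : oh * k, : ow * k] = expanded
        return dx


class GlobalAvgPool(Module):
    """Spatial mean per channel: (N,C,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w) * np.ones(1, dtype=grad.dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "fc", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(6.0 / (in_features + out_features))
        w = rng.uniform(-bound, bound, size=(out_features, in_features))
        self.weight = Parameter(f"{name}.weight", w.astype(dtype))
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T.astype(x.dtype) + self.bias.value.astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += (grad.T @ self._x).astype(self.weight.grad.dtype)
        self.bias.grad += grad.sum(axis=0).astype(self.bias.grad.dtype)
        return grad @ self.weight.value.astype(grad.dtype)
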