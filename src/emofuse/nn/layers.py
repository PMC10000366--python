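"""Minimal neural-network layers with explicit forward/backward passes.

The package's networks are small 1-D/2-D convolutional stacks trained with
plain stochastic gradient descent, so the engine is deliberately compact:
each layer owns its parameter dict and gradient dict, forward caches what
backward needs, and `Sequential` chains them. Convolutions are "valid"
(no zero padding) unless a pad is requested, matching the feature
extractors used here. All randomness (weight init, dropout masks) flows
through numpy Generators supplied by the caller.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv1D",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool1D",
    "MaxPool2D",
    "GlobalAvgPool1D",
    "GlobalMaxPool2D",
    "GlobalAvgPool2D",
    "Dropout",
    "Linear",
    "Flatten",
    "Sequential",
    "xavier_uniform",
]


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float64) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad

    def children(self) -> list["Layer"]:
        return []

    def n_params(self) -> int:
        own = int(sum(p.size for p in self.params.values()))
        return own + sum(c.n_params() for c in self.children())

    def parameters(self):
        """Yield (layer, name, array) triples for every learnable array."""
        for name in self.params:
            yield self, name, self.params[name]
        for child in self.children():
            yield from child.parameters()


class Conv1D(Layer):
    """Valid (no padding) 1-D convolution over (batch, channels, length)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 stride: int = 1, rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, kernel_size, stride
        w = xavier_uniform(rng, (c_out, c_in * kernel_size),
                           c_in * kernel_size, c_out * kernel_size, dtype)
        self.params = {"W": w, "b": np.zeros(c_out, dtype=dtype)}

    def forward(self, x, train=False, rng=None):
        b, c, length = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        if length < self.k:
            raise ValueError(f"input length {length} shorter than kernel {self.k}")
        win = sliding_window_view(x, self.k, axis=2)[:, :, :: self.stride]
        # (B, C, Lout, k) -> (B, Lout, C*k)
        cols = win.transpose(0, 2, 1, 3).reshape(b, -1, self.c_in * self.k)
        self._cols, self._in_shape = cols, x.shape
        out = cols @ self.params["W"].T + self.params["b"]
        return np.ascontiguousarray(out.transpose(0, 2, 1))

    def backward(self, grad):
        b, _, l_out = grad.shape
        g = grad.transpose(0, 2, 1)  # (B, Lout, c_out)
        gm = g.reshape(-1, self.c_out)
        self.grads["W"] = gm.T @ self._cols.reshape(-1, self.c_in * self.k)
        self.grads["b"] = gm.sum(axis=0)
        dcols = g @ self.params["W"]  # (B, Lout, C*k)
        dcols = dcols.reshape(b, l_out, self.c_in, self.k)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        for j in range(self.k):
            dx[:, :, j : j + l_out * self.stride : self.stride] += (
                dcols[:, :, :, j].transpose(0, 2, 1)
            )
        return dx


class Conv2D(Layer):
    """2-D convolution over (batch, channels, H, W) with optional padding."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 stride: int = 1, pad: int = 0,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.k, self.stride, self.pad = kernel_size, stride, pad
        fan_in = c_in * kernel_size * kernel_size
        w = xavier_uniform(rng, (c_out, fan_in), fan_in,
                           c_out * kernel_size * kernel_size, dtype)
        self.params = {"W": w, "b": np.zeros(c_out, dtype=dtype)}

    def forward(self, x, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                           (self.pad, self.pad)))
        b, c, h, w = x.shape
        win = sliding_window_view(x, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(
            b, ho * wo, self.c_in * self.k * self.k)
        self._cols, self._padded_shape, self._out_hw = cols, x.shape, (ho, wo)
        out = cols @ self.params["W"].T + self.params["b"]
        return np.ascontiguousarray(
            out.reshape(b, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, grad):
        b = grad.shape[0]
        ho, wo = self._out_hw
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.grads["W"] = g.T @ self._cols.reshape(-1, self._cols.shape[-1])
        self.grads["b"] = g.sum(axis=0)
        dcols = (g @ self.params["W"]).reshape(b, ho, wo, self.c_in,
                                               self.k, self.k)
        dxp = np.zeros(self._padded_shape, dtype=grad.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class BatchNorm(Layer):
    """Per-channel normalization with learnable scale and shift.

    Works for (B, C, L) and (B, C, H, W) inputs; statistics are taken over
    batch and spatial axes. Contributes exactly 2 learnable scalars per
    channel — running statistics are buffers, not parameters.
    """

    def __init__(self, n_channels: int, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float64) -> None:
        super().__init__()
        self.n_channels, self.eps, self.momentum = n_channels, eps, momentum
        self.params = {"gamma": np.ones(n_channels, dtype=dtype),
                       "beta": np.zeros(n_channels, dtype=dtype)}
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)

    def _bshape(self, ndim):
        return (1, self.n_channels) + (1,) * (ndim - 2)

    def forward(self, x, train=False, rng=None):
        axes = tuple(i for i in range(x.ndim) if i != 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        shp = self._bshape(x.ndim)
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) / std.reshape(shp)
        self._xhat, self._std, self._axes = xhat, std, axes
        return self.params["gamma"].reshape(shp) * xhat + \
            self.params["beta"].reshape(shp)

    def backward(self, grad):
        shp = self._bshape(grad.ndim)
        axes = self._axes
        n = grad.size / self.n_channels
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = self.params["gamma"].reshape(shp)
        dxhat = grad * g
        dx = (dxhat
              - dxhat.mean(axis=axes, keepdims=True)
              - self._xhat * (dxhat * self._xhat).sum(axis=axes,
                                                      keepdims=True) / n)
        return dx / self._std.reshape(shp)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Max pooling over the time axis; trailing remainder is dropped."""

    def __init__(self, size: int = 2, stride: int | None = None) -> None:
        super().__init__()
        self.size = size
        self.stride = stride if stride is not None else size
        if self.stride != self.size:
            raise NotImplementedError("only non-overlapping pooling supported")

    def forward(self, x, train=False, rng=None):
        b, c, length = x.shape
        lo = length // self.size
        xt = x[:, :, : lo * self.size].reshape(b, c, lo, self.size)
        self._arg = xt.argmax(axis=3)
        self._in_shape = x.shape
        return xt.max(axis=3)

    def backward(self, grad):
        b, c, lo = grad.shape
        dxt = np.zeros((b, c, lo, self.size), dtype=grad.dtype)
        np.put_along_axis(dxt, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, :, : lo * self.size] = dxt.reshape(b, c, lo * self.size)
        return dx


class MaxPool2D(Layer):
    """Spatial max pooling with stride = window (optionally padded)."""

    def __init__(self, size: int = 2, stride: int | None = None,
                 pad: int = 0) -> None:
        super().__init__()
        self.size = size
        self.stride = stride if stride is not None else size
        self.pad = pad

    def forward(self, x, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad),
                           (self.pad, self.pad)),
                       constant_values=-np.inf)
        win = sliding_window_view(x, (self.size, self.size), axis=(2, 3))
        win = win[:, :, :: self.stride, :: self.stride]
        b, c, ho, wo = win.shape[:4]
        flat = win.reshape(b, c, ho, wo, -1)
        self._arg = flat.argmax(axis=4)
        self._x_shape = x.shape
        return flat.max(axis=4)

    def backward(self, grad):
        b, c, ho, wo = grad.shape
        dxp = np.zeros(self._x_shape, dtype=grad.dtype)
        ii, jj = np.unravel_index(self._arg, (self.size, self.size))
        bi = np.arange(b)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        hi = np.arange(ho)[None, None, :, None] * self.stride + ii
        wi = np.arange(wo)[None, None, None, :] * self.stride + jj
        np.add.at(dxp, (bi, ci, hi, wi), grad)
        if self.pad:
            return dxp[:, :, self.pad:-self.pad, self.pad:-self.pad]
        return dxp


class GlobalAvgPool1D(Layer):
    """Mean over time: (B, C, L) -> (B, C)."""

    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=2)

    def backward(self, grad):
        b, c, length = self._in_shape
        return np.broadcast_to(grad[:, :, None] / length,
                               self._in_shape).copy()


class GlobalAvgPool2D(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._in_shape
        return np.broadcast_to(grad[:, :, None, None] / (h * w),
                               self._in_shape).copy()


class GlobalMaxPool2D(Layer):
    def forward(self, x, train=False, rng=None):
        b, c = x.shape[:2]
        flat = x.reshape(b, c, -1)
        self._arg, self._in_shape = flat.argmax(axis=2), x.shape
        return flat.max(axis=2)

    def backward(self, grad):
        b, c = grad.shape
        dflat = np.zeros((b, c, int(np.prod(self._in_shape[2:]))),
                         dtype=grad.dtype)
        np.put_along_axis(dflat, self._arg[..., None], grad[..., None], axis=2)
        return dflat.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {"W": xavier_uniform(rng, (d_out, d_in), d_in, d_out,
                                           dtype),
                       "b": np.zeros(d_out, dtype=dtype)}

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"]


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def children(self) -> list[Layer]:
        return self.layers
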