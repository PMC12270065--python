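"""Layers operating on (N, C, D, H, W) float arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float64


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.decay = decay      # weight decay applies (False for biases/affine)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, D, H, W) -> (N*D*H*W, C*k^3) patches with 'same' zero padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    n, c, d, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                                ).reshape(n * d * h * w, c * k ** 3)


def _conv3d_same(x: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Stride-1 'same' cross-correlation; weight (Cout, Cin, k, k, k)."""
    cout, cin, k, _, _ = weight.shape
    n, c, d, h, w = x.shape
    cols = _im2col(x, k)
    out = cols @ weight.reshape(cout, -1).T
    return out.reshape(n, d, h, w, cout).transpose(0, 4, 1, 2, 3)


class Conv3d(Layer):
    """Stride-1 'same' 3D convolution with He-style initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size ** 3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels) + (kernel_size,) * 3)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels), decay=False) if bias else None
        self.k = kernel_size
        self._x: np.ndarray | None = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x):
        self._x = x
        out = _conv3d_same(x, self.weight.value)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None, None]
        return out

    def backward(self, grad):
        x = self._x
        n, _, d, h, w = x.shape
        cout = self.weight.value.shape[0]
        g_cols = grad.transpose(0, 2, 3, 4, 1).reshape(n * d * h * w, cout)
        cols = _im2col(x, self.k)
        self.weight.grad += (g_cols.T @ cols).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=(0, 2, 3, 4))
        # input gradient: correlate grad with spatially flipped, transposed kernel
        w_t = np.flip(self.weight.value, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
        return _conv3d_same(grad, np.ascontiguousarray(w_t))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over the spatial volume."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma.value[None, :, None, None, None] * self._xhat \
            + self.beta.value[None, :, None, None, None]

    def backward(self, grad):
        xhat, istd = self._xhat, self._istd
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3, 4))
        self.beta.grad += grad.sum(axis=(0, 2, 3, 4))
        g = grad * self.gamma.value[None, :, None, None, None]
        m1 = g.mean(axis=(2, 3, 4), keepdims=True)
        m2 = (g * xhat).mean(axis=(2, 3, 4), keepdims=True)
        return istd * (g - m1 - xhat * m2)


class AvgPool3d(Layer):
    """2x2x2 average pooling; spatial dims must be even."""

    def forward(self, x):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"AvgPool3d needs even spatial dims, got {(d, h, w)}")
        self._shape = x.shape
        return x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def backward(self, grad):
        g = grad[:, :, :, None, :, None, :, None] / 8.0
        return np.broadcast_to(
            g, grad.shape[:2] + (grad.shape[2], 2, grad.shape[3], 2, grad.shape[4], 2)
        ).reshape(self._shape)


class Upsample3d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, grad):
        n, c, d, h, w = grad.shape
        return grad.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
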