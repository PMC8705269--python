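"""Minimal feed-forward layer framework with manual backpropagation.

Implements exactly the pieces the encoder architectures need: 1-D
convolution (im2col + GEMM), non-overlapping max pooling, fully-connected
layers, leaky ReLU, flattening, a Sequential container, softmax
cross-entropy and the Adam optimizer.  Weights use Kaiming-uniform fan-in
initialization with the leaky-ReLU gain; float32 by default (float64 is used
in gradient-check tests).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """One trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


def _kaiming_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                     fan_in: int, slope: float, dtype) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + slope**2))
    bound = gain * np.sqrt(3.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


class Conv1d(Layer):
    """1-D convolution (cross-correlation) over (N, C, L) input."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 padding: int = 0, stride: int = 1,
                 rng: np.random.Generator | None = None, slope: float = 0.01,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = padding
        self.stride = stride
        fan_in = in_channels * kernel_size
        self.weight = Param(
            _kaiming_uniform(rng, (out_channels, in_channels, kernel_size),
                             fan_in, slope, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cache = None

    def out_length(self, length: int) -> int:
        return (length + 2 * self.padding - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        win = sliding_window_view(xp, self.kernel_size, axis=2)[:, :, ::self.stride]
        l_out = win.shape[2]
        cols = win.transpose(0, 2, 1, 3).reshape(n * l_out, c * self.kernel_size)
        w2 = self.weight.data.reshape(self.out_channels, -1)
        out = cols @ w2.T + self.bias.data
        self._cache = (cols, (n, c, length), l_out)
        return out.reshape(n, l_out, self.out_channels).transpose(0, 2, 1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, (n, c, length), l_out = self._cache
        k, p, s = self.kernel_size, self.padding, self.stride
        g2 = grad.transpose(0, 2, 1).reshape(n * l_out, self.out_channels)
        self.weight.grad += (g2.T @ cols).reshape(self.weight.data.shape)
        self.bias.grad += g2.sum(axis=0)
        dcols = (g2 @ self.weight.data.reshape(self.out_channels, -1))
        dwin = dcols.reshape(n, l_out, c, k).transpose(0, 2, 1, 3)
        dxp = np.zeros((n, c, length + 2 * p), dtype=grad.dtype)
        for j in range(k):
            dxp[:, :, j : j + (l_out - 1) * s + 1 : s] += dwin[:, :, :, j]
        return dxp[:, :, p : p + length] if p else dxp

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel == stride, floor division)."""

    def __init__(self, kernel_size: int):
        self.kernel_size = kernel_size
        self._cache = None

    def out_length(self, length: int) -> int:
        return length // self.kernel_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        k = self.kernel_size
        l_out = length // k
        xr = x[:, :, : l_out * k].reshape(n, c, l_out, k)
        arg = xr.argmax(axis=3)
        self._cache = (arg, (n, c, length), l_out)
        return np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, (n, c, length), l_out = self._cache
        k = self.kernel_size
        dxr = np.zeros((n, c, l_out, k), dtype=grad.dtype)
        np.put_along_axis(dxr, arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, length), dtype=grad.dtype)
        dx[:, :, : l_out * k] = dxr.reshape(n, c, l_out * k)
        return dx


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, slope: float = 0.01,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(
            _kaiming_uniform(rng, (out_features, in_features), in_features,
                             slope, dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"expected {self.in_features} input features, got {x.shape[1]}")
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.parameters()]


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the raw scores."""
    n = scores.shape[0]
    probs = softmax(scores.astype(np.float64))
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(scores.dtype)


class Adam:
    """Adam optimizer; ``lr`` is mutable so a scheduler can adjust it."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
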