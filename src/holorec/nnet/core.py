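"""Minimal NumPy building blocks for small convolutional networks.

Implements exactly what the reconstruction network needs — 3x3 same-padding
convolutions (im2col), ReLU, 2x2 average pooling, nearest-neighbour
upsampling, residual blocks and an Adam optimizer — with explicit
forward/backward passes. Arrays are NCHW float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Conv2d",
    "ReLU",
    "AvgPool2",
    "Upsample2",
    "Sequential",
    "ResidualBlock",
    "Adam",
    "mse_loss",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Module:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) with same (zero) padding, stride 1."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i * k + j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    n, c, h, w = shape
    p = k // 2
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    cols = cols.reshape(n, c, k * k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, i * k + j]
    return xp[:, :, p : p + h, p : p + w]


class Conv2d(Module):
    """3x3 (or kxk) convolution with same padding and stride 1."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        if in_channels <= 0 or out_channels <= 0 or kernel_size <= 0:
            raise ValueError("channel counts and kernel size must be positive")
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd (same padding)")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, fan_in))
        else:
            rng = rng or np.random.default_rng()
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels))
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        cols = _im2col(x, self.k)
        self._cols, self._xshape = cols, x.shape
        out = np.matmul(self.weight.value, cols)  # (N, cout, H*W)
        out += self.bias.value[None, :, None]
        return out.reshape(n, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._xshape
        dyf = dy.reshape(n, self.cout, h * w)
        self.weight.grad += np.einsum("nof,ncf->oc", dyf, self._cols, optimize=True)
        self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, dyf)
        self._cols = None
        return _col2im(dcols, self._xshape, self.k)

    @property
    def n_params(self) -> int:
        return self.weight.value.size + self.bias.value.size


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class AvgPool2(Module):
    """2x2 average pooling (spatial dims must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial size ({h},{w}) not divisible by 2")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
        return up / 4.0


class Upsample2(Module):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class ResidualBlock(Module):
    """y = relu(x + conv(relu(conv(x)))), channel-preserving."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = Conv2d(channels, channels, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, rng)
        self.relu_out = ReLU()

    def parameters(self) -> list[Parameter]:
        return self.conv1.parameters() + self.conv2.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2(self.relu1(self.conv1(x)))
        return self.relu_out(x + y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        dx_branch = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        return dsum + dx_branch


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = 2.0 * diff / diff.size
    return loss, grad
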