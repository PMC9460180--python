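"""Minimal NumPy neural-network layers with explicit backpropagation.

Every layer implements ``forward(x, train)`` and ``backward(grad_out)``;
``backward`` must be called with the gradient of the loss with respect to the
layer's most recent output and returns the gradient with respect to its input.
Parameters are :class:`Param` objects whose ``grad`` buffers are accumulated by
``backward`` and consumed by an optimizer.

Shapes follow the 1D convolutional convention ``(batch, channels, length)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Identity",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Dropout",
    "Linear",
    "Sequential",
]


class Param:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _pad_amounts(kernel_size: int, padding: int | str) -> tuple[int, int]:
    """Resolve padding to (left, right) sample counts.

    ``"same"`` preserves length at stride 1; for even kernels the extra pad
    sample goes on the right.
    """
    if padding == "same":
        total = kernel_size - 1
        return total // 2, total - total // 2
    if padding == "valid":
        return 0, 0
    return int(padding), int(padding)


class Conv1d(Layer):
    """1D cross-correlation over (B, C_in, L) inputs.

    Implemented as a sum of per-tap matrix products, which maps well onto
    BLAS for the short kernels used here (k <= 16).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.pad_l, self.pad_r = _pad_amounts(kernel_size, padding)
        rng = rng or np.random.default_rng()
        # He initialization (fan_in = C_in * k), suited to ReLU stacks
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size))
        self.weight = Param(w.astype(dtype), "conv.weight")
        self.bias = Param(np.zeros(out_channels, dtype=dtype), "conv.bias") if bias else None
        self._cache: tuple | None = None

    def out_length(self, n: int) -> int:
        return (n + self.pad_l + self.pad_r - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, n = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad_l, self.pad_r))) if (self.pad_l or self.pad_r) else x
        lo = self.out_length(n)
        if lo < 1:
            raise ValueError(f"input length {n} too short for kernel {self.kernel_size}")
        w = self.weight.data
        out = np.zeros((b, self.out_channels, lo), dtype=x.dtype)
        s = self.stride
        for j in range(self.kernel_size):
            out += np.matmul(w[:, :, j], xp[:, :, j : j + s * lo : s])
        if self.bias is not None:
            out += self.bias.data[None, :, None]
        self._cache = (xp, x.shape, lo)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xp, x_shape, lo = self._cache
        w = self.weight.data
        s = self.stride
        dxp = np.zeros_like(xp)
        for j in range(self.kernel_size):
            sl = slice(j, j + s * lo, s)
            # dW[o,c,j] = sum_{b,t} grad[b,o,t] * xp[b,c,t*s+j]
            self.weight.grad[:, :, j] += np.einsum("bot,bct->oc", grad_out, xp[:, :, sl], optimize=True)
            dxp[:, :, sl] += np.matmul(w[:, :, j].T, grad_out)
        if self.bias is not None:
            self.bias.grad += grad_out.sum(axis=(0, 2))
        if self.pad_l or self.pad_r:
            dxp = dxp[:, :, self.pad_l : self.pad_l + x_shape[2]]
        return dxp

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length) with running stats."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2))
        self.beta.grad += grad_out.sum(axis=(0, 2))
        g = grad_out * self.gamma.data[None, :, None]
        if not train:
            return g * inv_std[None, :, None]
        n = shape[0] * shape[2]
        # standard batch-norm backward in terms of xhat
        sum_g = g.sum(axis=(0, 2), keepdims=True).reshape(1, -1, 1)
        sum_gx = (g * xhat).sum(axis=(0, 2), keepdims=True).reshape(1, -1, 1)
        return (inv_std[None, :, None] / n) * (n * g - sum_g - xhat * sum_gx)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class Identity(Layer):
    """Pass-through; stands in for ReLU in linearity-test variants."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out


class MaxPool1d(Layer):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0) -> None:
        self.kernel_size = kernel_size
        self.stride = stride if stride is not None else kernel_size
        self.padding = padding

    def out_length(self, n: int) -> int:
        return (n + 2 * self.padding - self.kernel_size) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, n = x.shape
        if self.padding:
            xp = np.full((b, c, n + 2 * self.padding), -np.inf, dtype=x.dtype)
            xp[:, :, self.padding : self.padding + n] = x
        else:
            xp = x
        lo = self.out_length(n)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel_size, axis=2)[:, :, :: self.stride]
        win = win[:, :, :lo]
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, xp.shape, x.shape, lo)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        idx, xp_shape, x_shape, lo = self._cache
        b, c, _ = x_shape
        dxp = np.zeros(xp_shape, dtype=grad_out.dtype)
        starts = np.arange(lo) * self.stride
        flat_pos = starts[None, None, :] + idx  # absolute position in padded input
        bi = np.arange(b)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dxp, (bi, ci, flat_pos), grad_out)
        if self.padding:
            dxp = dxp[:, :, self.padding : self.padding + x_shape[2]]
        return dxp


class GlobalAvgPool1d(Layer):
    """Reduce (B, C, L) -> (B, C) by the positional mean of each channel."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._n = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return np.repeat(grad_out[:, :, None], self._n, axis=2) / self._n


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad_out
        return grad_out * self._mask.astype(grad_out.dtype)


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Param(rng.uniform(-bound, bound, (out_features, in_features)).astype(dtype), "linear.weight")
        self.bias = Param(np.zeros(out_features, dtype=dtype), "linear.bias")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.weight.grad += grad_out.T @ self._x
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.data

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out
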