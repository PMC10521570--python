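"""Minimal CPU layer library with reverse-mode gradients.

The segmentation networks in this package need a small, fixed vocabulary of
layers: 2-D convolution (stride 1, "same" padding), batch normalisation,
ReLU, 2x2 max-pooling, parameter-free 2x nearest-neighbour upsampling,
dropout and a sigmoid head. Each layer implements ``forward`` (caching what
backward needs) and ``backward`` (returning the gradient w.r.t. its input
and accumulating gradients on its parameters).

Arrays are NHWC ``float32`` throughout: convolution lowers to an im2col
matrix product so the heavy lifting is a single BLAS GEMM per layer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ShapeError

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "BatchNorm",
    "ReLU",
    "MaxPool2x2",
    "Upsample2x",
    "Dropout",
    "Sigmoid",
]


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: parameter bookkeeping plus the forward/backward contract."""

    name: str = ""

    def params(self) -> list[Param]:
        return []

    def non_trainable_arrays(self) -> list[np.ndarray]:
        """Stateful arrays that are tracked but never gradient-updated."""
        return []

    def n_trainable(self) -> int:
        return sum(p.size for p in self.params())

    def n_non_trainable(self) -> int:
        return sum(int(a.size) for a in self.non_trainable_arrays())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """k x k convolution, stride 1, zero ("same") padding, NHWC.

    Weights are He-normal initialised (std = sqrt(2 / fan_in)), the
    conventional choice for ReLU networks. 1x1 kernels skip the im2col
    step and multiply channel vectors directly. Even kernels pad
    asymmetrically (one extra row/column at the bottom/right), matching
    the usual "same" convention, so output spatial dims always equal input.
    """

    def __init__(self, cin: int, cout: int, kernel: int, *, bias: bool = True,
                 rng: np.random.Generator, name: str = "conv"):
        self.name = name
        self.kernel = kernel
        self.cin, self.cout = cin, cout
        fan_in = kernel * kernel * cin
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, cin, cout))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(cout)) if bias else None
        self._cache = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.cin:
            raise ShapeError(f"{self.name}: expected {self.cin} input channels, got {x.shape[-1]}")
        B, H, W, C = x.shape
        k = self.kernel
        wmat = self.w.value.reshape(k * k * C, self.cout)
        if k == 1:
            cols = x.reshape(-1, C)
        else:
            lo, hi = (k - 1) // 2, k // 2
            xp = np.pad(x, ((0, 0), (lo, hi), (lo, hi), (0, 0)))
            win = sliding_window_view(xp, (k, k), axis=(1, 2))  # B,H,W,C,k,k
            cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(-1, k * k * C)
        out = cols @ wmat
        if self.b is not None:
            out += self.b.value
        self._cache = (x.shape, cols)
        return out.reshape(B, H, W, self.cout)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, H, W, C), cols = self._cache
        k = self.kernel
        df = dout.reshape(-1, self.cout)
        self.w.grad += (cols.T @ df).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += df.sum(axis=0)
        dcols = df @ self.w.value.reshape(-1, self.cout).T
        if k == 1:
            return dcols.reshape(B, H, W, C)
        lo, hi = (k - 1) // 2, k // 2
        dcols = dcols.reshape(B, H, W, k, k, C)
        dxp = np.zeros((B, H + lo + hi, W + lo + hi, C), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, i, j, :]
        return dxp[:, lo:lo + H, lo:lo + W, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, height, width).

    gamma/beta are trainable (2C); the running mean/variance used at
    inference are tracked but not gradient-updated (2C non-trainable).
    """

    def __init__(self, channels: int, *, eps: float = 1e-3, momentum: float = 0.99,
                 name: str = "bn"):
        self.name = name
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def non_trainable_arrays(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.shape[-1] != self.channels:
            raise ShapeError(f"{self.name}: expected {self.channels} channels, got {x.shape[-1]}")
        if training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            m = self.momentum
            self.running_mean[:] = m * self.running_mean + (1 - m) * mean
            self.running_var[:] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std.astype(np.float32), training)
        return (self.gamma.value * xhat + self.beta.value).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, training = self._cache
        axes = (0, 1, 2)
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if not training:
            return dout * (self.gamma.value * inv_std)
        n = dout.shape[0] * dout.shape[1] * dout.shape[2]
        return (self.gamma.value * inv_std / n) * (n * dout - dbeta - xhat * dgamma)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; requires even spatial dims."""

    def __init__(self, name: str = "pool"):
        self.name = name
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, H, W, C = x.shape
        if H % 2 or W % 2:
            raise ShapeError(f"{self.name}: spatial dims must be even, got {H}x{W}")
        win = x.reshape(B, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 2, 4, 5)
        win = win.reshape(B, H // 2, W // 2, 4, C)
        idx = win.argmax(axis=3)
        self._cache = (x.shape, idx)
        return np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (B, H, W, C), idx = self._cache
        dwin = np.zeros((B, H // 2, W // 2, 4, C), dtype=np.float32)
        np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        return dwin.reshape(B, H // 2, W // 2, 2, 2, C).transpose(0, 1, 3, 2, 4, 5).reshape(B, H, W, C)


class Upsample2x(Layer):
    """Parameter-free 2x nearest-neighbour upsampling."""

    def __init__(self, name: str = "up"):
        self.name = name

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = dout.shape
        return dout.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, *, rng: np.random.Generator, name: str = "dropout"):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"{name}: rate must be in [0, 1), got {rate}")
        self.name = name
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sigmoid(Layer):
    def __init__(self, name: str = "sigmoid"):
        self.name = name
        self._out = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # clip to keep exp finite in float32
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))
        return self._out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return (dout * self._out * (1.0 - self._out)).astype(np.float32)
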