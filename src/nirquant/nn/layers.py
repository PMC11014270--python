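"""Minimal 1-D neural-network layers with explicit forward/backward passes.

Everything runs in float64 on numpy. Convolutional activations use the
(N, C, L) layout; dense activations use (N, D). Each layer caches what its
backward pass needs during ``forward(..., training=True)``; ``backward``
accumulates parameter gradients and returns the gradient w.r.t. its input.

Weight initialization is a uniform fan-in scheme, U(-1/sqrt(fan_in),
1/sqrt(fan_in)), keyed to the generator passed at construction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError


class Parameter:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Layer:
    def forward(self, x, training=False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def out_shape(self, shape):
        """(C, L) or (D,) shape arithmetic; raises ConfigurationError if invalid."""
        return shape


def _pad_amount(L: int, kernel: int, stride: int, padding) -> tuple[int, int]:
    """(left, right) padding; ``padding`` is an int or 'same'."""
    if padding == "same":
        out = -(-L // stride)  # ceil
        total = max((out - 1) * stride + kernel - L, 0)
        return total // 2, total - total // 2
    return int(padding), int(padding)


class Conv1D(Layer):
    def __init__(self, in_channels, out_channels, kernel, stride=1, padding=0,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride, self.padding = kernel, stride, padding
        fan_in = in_channels * kernel
        self.W = Parameter(_uniform_fan_in(rng, (fan_in, out_channels), fan_in))
        self.b = Parameter(_uniform_fan_in(rng, (out_channels,), fan_in))
        self._cache = None

    def parameters(self):
        return [self.W, self.b]

    def out_shape(self, shape):
        C, L = shape
        if C != self.in_channels:
            raise ConfigurationError(
                f"Conv1D expected {self.in_channels} channels, got {C}")
        pl, pr = _pad_amount(L, self.kernel, self.stride, self.padding)
        Lp = L + pl + pr
        if Lp < self.kernel:
            raise ConfigurationError(
                f"input length {L} too short for kernel {self.kernel}")
        return (self.out_channels, (Lp - self.kernel) // self.stride + 1)

    def forward(self, x, training=False):
        N, C, L = x.shape
        pl, pr = _pad_amount(L, self.kernel, self.stride, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride]
        # (N, C, Lout, k) -> (N, Lout, C*k)
        cols = win.transpose(0, 2, 1, 3).reshape(N, win.shape[2], C * self.kernel)
        out = cols @ self.W.data + self.b.data
        if training:
            self._cache = (cols, xp.shape, (pl, pr), x.shape)
        return out.transpose(0, 2, 1)

    def backward(self, dout):
        cols, xp_shape, (pl, pr), x_shape = self._cache
        N, Lout, _ = cols.shape
        dt = dout.transpose(0, 2, 1)  # (N, Lout, F)
        self.W.grad += np.einsum("nlp,nlf->pf", cols, dt)
        self.b.grad += dt.sum(axis=(0, 1))
        dcols = dt @ self.W.data.T  # (N, Lout, C*k)
        C = self.in_channels
        dcols = dcols.reshape(N, Lout, C, self.kernel).transpose(0, 2, 1, 3)
        dxp = np.zeros(xp_shape)
        for kk in range(self.kernel):
            stop = kk + (Lout - 1) * self.stride + 1
            dxp[:, :, kk:stop:self.stride] += dcols[:, :, :, kk]
        return dxp[:, :, pl:xp_shape[2] - pr] if (pl or pr) else dxp


class MaxPool1D(Layer):
    def __init__(self, size=2, stride=None, padding=0):
        self.size = size
        self.stride = stride or size
        self.padding = padding
        self._cache = None

    def out_shape(self, shape):
        C, L = shape
        pl, pr = _pad_amount(L, self.size, self.stride, self.padding)
        Lp = L + pl + pr
        if Lp < self.size:
            raise ConfigurationError(f"input length {L} too short for pool {self.size}")
        out = (Lp - self.size) // self.stride + 1
        if out < 1:
            raise ConfigurationError(f"input length {L} too short for pool {self.size}")
        return (C, out)

    def forward(self, x, training=False):
        N, C, L = x.shape
        pl, pr = _pad_amount(L, self.size, self.stride, self.padding)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=-np.inf) \
            if (pl or pr) else x
        win = sliding_window_view(xp, self.size, axis=2)[:, :, ::self.stride]
        arg = win.argmax(axis=3)
        out = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]
        if training:
            self._cache = (arg, xp.shape, (pl, pr), L)
        return out

    def backward(self, dout):
        arg, xp_shape, (pl, pr), L = self._cache
        N, C, Lout = dout.shape
        dxp = np.zeros(xp_shape)
        ni, ci, li = np.ogrid[:N, :C, :Lout]
        pos = li * self.stride + arg
        np.add.at(dxp, (ni, ci, pos), dout)
        return dxp[:, :, pl:xp_shape[2] - pr] if (pl or pr) else dxp


class ReLU(Layer):
    def forward(self, x, training=False):
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class BatchNorm1D(Layer):
    """Per-channel normalization over (batch, length) for (N, C, L) input."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        g = self.gamma.data[None, :, None]
        b = self.beta.data[None, :, None]
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
            self._cache = (xhat, inv_std)
            return g * xhat + b
        xhat = (x - self.running_mean[None, :, None]) / \
            np.sqrt(self.running_var[None, :, None] + self.eps)
        return g * xhat + b

    def backward(self, dout):
        xhat, inv_std = self._cache
        N, C, L = dout.shape
        m = N * L
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        dxhat = dout * self.gamma.data[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * dxhat - s1 - xhat * s2)


class Flatten(Layer):
    def out_shape(self, shape):
        C, L = shape
        return (C * L,)

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class GlobalAvgPool1D(Layer):
    def out_shape(self, shape):
        return (shape[0],)

    def forward(self, x, training=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Dense(Layer):
    def __init__(self, in_features, out_features, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        self.W = Parameter(_uniform_fan_in(rng, (in_features, out_features), in_features))
        self.b = Parameter(_uniform_fan_in(rng, (out_features,), in_features))

    def parameters(self):
        return [self.W, self.b]

    def out_shape(self, shape):
        if shape != (self.in_features,):
            raise ConfigurationError(
                f"Dense expected {self.in_features} features, got {shape}")
        return (self.out_features,)

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.W.data + self.b.data

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.data.T


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def out_shape(self, shape):
        for layer in self.layers:
            shape = layer.out_shape(shape)
        return shape

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Layer):
    """Pre-activation residual block: out = shortcut(x) + f(x) with

    f = BN -> ReLU -> Conv(k3, same) -> BN -> ReLU -> Conv(k3, same)

    The shortcut is the identity when channels match (so zeroing the block's
    convolution weights makes the block an exact identity) and a 1x1
    projection convolution when they change.
    """

    def __init__(self, in_channels, out_channels, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.main = Sequential(
            BatchNorm1D(in_channels), ReLU(),
            Conv1D(in_channels, out_channels, 3, padding="same", rng=rng),
            BatchNorm1D(out_channels), ReLU(),
            Conv1D(out_channels, out_channels, 3, padding="same", rng=rng),
        )
        self.projection = None if in_channels == out_channels else \
            Conv1D(in_channels, out_channels, 1, rng=rng)

    @property
    def convs(self) -> list[Conv1D]:
        return [l for l in self.main.layers if isinstance(l, Conv1D)]

    def parameters(self):
        ps = self.main.parameters()
        if self.projection is not None:
            ps += self.projection.parameters()
        return ps

    def out_shape(self, shape):
        return self.main.out_shape(shape)

    def forward(self, x, training=False):
        short = x if self.projection is None else self.projection.forward(x, training)
        return short + self.main.forward(x, training=training)

    def backward(self, dout):
        dx = self.main.backward(dout)
        dx = dx + (dout if self.projection is None else self.projection.backward(dout))
        return dx


class InceptionModule(Layer):
    """Parallel multi-scale branches concatenated on the channel axis.

    Branches: 1x1 conv, 3-wide conv (same), 5-wide conv (same), and max-pool
    (3, stride 1, same) followed by a 1x1 conv; each branch ends in ReLU.
    Output channels = sum of the branch channel counts.
    """

    def __init__(self, in_channels, c1, c3, c5, cpool,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.branches = [
            Sequential(Conv1D(in_channels, c1, 1, rng=rng), ReLU()),
            Sequential(Conv1D(in_channels, c3, 3, padding="same", rng=rng), ReLU()),
            Sequential(Conv1D(in_channels, c5, 5, padding="same", rng=rng), ReLU()),
            Sequential(MaxPool1D(3, stride=1, padding="same"),
                       Conv1D(in_channels, cpool, 1, rng=rng), ReLU()),
        ]
        self.branch_channels = (c1, c3, c5, cpool)

    def parameters(self):
        return [p for b in self.branches for p in b.parameters()]

    def out_shape(self, shape):
        outs = [b.out_shape(shape) for b in self.branches]
        return (sum(o[0] for o in outs), outs[0][1])

    def forward(self, x, training=False):
        return np.concatenate([b.forward(x, training=training) for b in self.branches],
                              axis=1)

    def backward(self, dout):
        dx = None
        start = 0
        for b, c in zip(self.branches, self.branch_channels):
            d = b.backward(dout[:, start:start + c])
            dx = d if dx is None else dx + d
            start += c
        return dx
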