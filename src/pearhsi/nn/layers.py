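"""Minimal 1-D neural-network layers on numpy with manual backpropagation.

Everything runs in float32 on a single thread; convolutions are lowered to a
single GEMM per layer via an im2col view, which is where essentially all the
training time goes.  Layer semantics (shapes, batch-norm statistics, LSTM gate
order i,f,g,o and two-bias convention) follow the conventions common to
mainstream deep-learning frameworks so that closed-form parameter counts and
published layer geometries carry over unchanged.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import GeometryError

DTYPE = np.float32


def conv1d_output_length(L: int, kernel: int, stride: int = 1, padding: int = 0) -> int:
    """floor((L + 2p - k)/s) + 1; raises GeometryError if no output remains."""
    if L <= 0 or kernel <= 0 or stride <= 0 or padding < 0:
        raise GeometryError("conv geometry arguments must be positive (padding >= 0)")
    out = (L + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise GeometryError(
            f"conv with k={kernel}, s={stride}, p={padding} on length {L} "
            "produces an empty output"
        )
    return out


class Parameter:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base: forward caches what backward needs; parameters are collected
    recursively from attributes."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for attr in self.__dict__.values():
            if isinstance(attr, Parameter):
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for attr in self.__dict__.values():
            if isinstance(attr, Module):
                attr.set_training(flag)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.set_training(flag)

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv1d(Module):
    """Cross-correlation over (N, C_in, L) -> (N, C_out, L_out)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, *, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels, kernel), fan_in), "conv.w")
        self.bias = Parameter(_fan_in_uniform(rng, (out_channels,), fan_in), "conv.b")

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int]:
        n, c, L = x.shape
        L_out = conv1d_output_length(L, self.kernel, self.stride, self.padding)
        if self.padding:
            xp = np.zeros((n, c, L + 2 * self.padding), dtype=DTYPE)
            xp[:, :, self.padding:self.padding + L] = x
        else:
            xp = x
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride]
        # (N, C, L_out, k) -> (N * L_out, C * k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
            n * L_out, c * self.kernel)
        return cols, L_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n = x.shape[0]
        cols, L_out = self._im2col(x)
        w2 = self.weight.value.reshape(self.out_channels, -1)
        y = cols @ w2.T + self.bias.value
        self._cache = (cols, x.shape, L_out)
        return np.ascontiguousarray(y.reshape(n, L_out, self.out_channels)
                                    .transpose(0, 2, 1))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, L_out = self._cache
        n, c, L = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        dyr = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(
            n * L_out, self.out_channels)
        self.weight.grad += (dyr.T @ cols).reshape(self.weight.value.shape)
        self.bias.grad += dyr.sum(axis=0)
        dcols = dyr @ self.weight.value.reshape(self.out_channels, -1)
        dwin = dcols.reshape(n, L_out, c, k).transpose(0, 2, 1, 3)  # (N,C,L_out,k)
        dxp = np.zeros((n, c, L + 2 * p), dtype=DTYPE)
        for kk in range(k):
            dxp[:, :, kk:kk + s * L_out:s] += dwin[:, :, :, kk]
        return dxp[:, :, p:p + L] if p else dxp


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_features, in_features), in_features), "fc.w")
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features), "fc.b")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._cache = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        dout = np.ascontiguousarray(dout, dtype=DTYPE)
        self.weight.grad += dout.T @ x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0).astype(DTYPE, copy=False)


class BatchNorm1d(Module):
    """Per-channel normalization over (N, C, L) or (N, C)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=DTYPE), "bn.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=DTYPE), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def _axes(self, x: np.ndarray):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x: np.ndarray):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        axes, shp = self._axes(x), self._shape(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // self.channels
            unbiased = var * m / max(m - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv_std.reshape(shp)
        self._cache = (xhat, inv_std)
        return (self.gamma.value.reshape(shp) * xhat
                + self.beta.value.reshape(shp)).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        axes, shp = self._axes(dout), self._shape(dout)
        m = dout.size // self.channels
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.value.reshape(shp)
        if not self.training:
            return (dout * g * inv_std.reshape(shp)).astype(DTYPE, copy=False)
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=axes).reshape(shp)
              - xhat * (dxhat * xhat).mean(axis=axes).reshape(shp))
        return (dx * inv_std.reshape(shp)).astype(DTYPE, copy=False)


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.padding = padding

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, L = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        L_out = conv1d_output_length(L, k, s, p)
        if p:
            xp = np.full((n, c, L + 2 * p), -np.inf, dtype=DTYPE)
            xp[:, :, p:p + L] = x
        else:
            xp = x
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s]  # (N, C, L_out, k)
        idx = win.argmax(axis=3)
        self._cache = (idx, x.shape, L_out)
        return np.ascontiguousarray(np.take_along_axis(win, idx[..., None], axis=3)[..., 0])

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, x_shape, L_out = self._cache
        n, c, L = x_shape
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros((n, c, L + 2 * p), dtype=DTYPE)
        for kk in range(k):
            mask = idx == kk
            dxp[:, :, kk:kk + s * L_out:s] += np.where(mask, dout, 0)
        return dxp[:, :, p:p + L] if p else dxp


class GlobalAvgPool1d(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._L, axis=2) / DTYPE(self._L)


class Flatten(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMCell(Module):
    """Single-layer LSTM applied to a length-1 sequence from zero state.

    Gate order (i, f, g, o); separate input/recurrent biases, so the parameter
    count is 4 * (in*hidden + hidden^2 + 2*hidden).
    """

    def __init__(self, input_size: int, hidden_size: int, *,
                 rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        h = hidden_size
        self.w_ih = Parameter(_fan_in_uniform(rng, (4 * h, input_size), h), "lstm.w_ih")
        self.w_hh = Parameter(_fan_in_uniform(rng, (4 * h, h), h), "lstm.w_hh")
        self.b_ih = Parameter(_fan_in_uniform(rng, (4 * h,), h), "lstm.b_ih")
        self.b_hh = Parameter(_fan_in_uniform(rng, (4 * h,), h), "lstm.b_hh")

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        h = self.hidden_size
        gates = x @ self.w_ih.value.T + self.b_ih.value + self.b_hh.value
        i = _sigmoid(gates[:, 0:h])
        f = _sigmoid(gates[:, h:2 * h])
        g = np.tanh(gates[:, 2 * h:3 * h])
        o = _sigmoid(gates[:, 3 * h:4 * h])
        c = i * g  # zero initial cell state: f * c0 vanishes
        tc = np.tanh(c)
        self._cache = (x, i, f, g, o, tc)
        return (o * tc).astype(DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, i, f, g, o, tc = self._cache
        do = dout * tc
        dc = dout * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = np.zeros_like(f)  # c0 == 0
        dgates = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1).astype(DTYPE, copy=False)
        self.w_ih.grad += dgates.T @ x
        # h0 == 0 so w_hh receives no gradient from a length-1 sequence
        self.b_ih.grad += dgates.sum(axis=0)
        self.b_hh.grad += dgates.sum(axis=0)
        return dgates @ self.w_ih.value


class Adam:
    """Adam optimizer with the conventional bias-corrected moments."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * (p.grad * p.grad)
            p.value -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(DTYPE)
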