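"""Minimal NumPy neural-network kernel: 1-D conv layers with hand-written
backpropagation and an Adam optimizer.

No autodiff backend is assumed; every layer implements ``forward`` /
``backward`` explicitly and is validated by finite-difference tests.
Array convention: activations are (batch, length, channels) for temporal
layers and (batch, features) after pooling.
"""

from __future__ import annotations

import numpy as np

from .errors import ArchitectureError


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    """Base layer: stateless by default, no parameters."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def own_params(self) -> list:
        return []

    def sublayers(self) -> list:
        return []

    def own_state(self) -> dict:
        return {}

    def load_own_state(self, state: dict) -> None:
        pass


def collect_params(layer: Layer) -> list:
    params = list(layer.own_params())
    for sub in layer.sublayers():
        params.extend(collect_params(sub))
    return params


def get_state(layer: Layer) -> list:
    """Flat copy of all parameters and buffers (e.g. BN running stats)."""
    state = [{k: v.copy() for k, v in layer.own_state().items()}]
    state.append([p.value.copy() for p in layer.own_params()])
    for sub in layer.sublayers():
        state.append(get_state(sub))
    return state


def set_state(layer: Layer, state: list) -> None:
    layer.load_own_state(state[0])
    for p, v in zip(layer.own_params(), state[1], strict=True):
        p.value[...] = v
    for sub, s in zip(layer.sublayers(), state[2:], strict=True):
        set_state(sub, s)


def flatten_state(state: list, out: list | None = None) -> list:
    """State tree -> flat list of arrays (for npz persistence)."""
    if out is None:
        out = []
    buf, params, *subs = state
    for k in sorted(buf):
        out.append(buf[k])
    out.extend(params)
    for s in subs:
        flatten_state(s, out)
    return out


def unflatten_state(template: list, arrays: list, pos: int = 0):
    buf, params, *subs = template
    new_buf = {}
    for k in sorted(buf):
        new_buf[k] = arrays[pos]
        pos += 1
    new_params = []
    for _ in params:
        new_params.append(arrays[pos])
        pos += 1
    new_subs = []
    for s in subs:
        sub_state, pos = unflatten_state(s, arrays, pos)
        new_subs.append(sub_state)
    return [new_buf, new_params, *new_subs], pos


class Conv1D(Layer):
    """1-D convolution with 'same'-style padding and integer stride.

    Requires the input length to be divisible by the stride; output
    length is exactly L // stride.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 use_bias: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (kernel * in_ch))
        self.w = Param(rng.normal(0.0, std, size=(kernel, in_ch, out_ch)))
        self.b = Param(np.zeros(out_ch)) if use_bias else None
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def own_params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _pads(self, L: int) -> tuple:
        if L % self.stride:
            raise ArchitectureError(
                f"input length {L} not divisible by stride {self.stride}")
        out_len = L // self.stride
        pad = max((out_len - 1) * self.stride + self.kernel - L, 0)
        return pad // 2, pad - pad // 2, out_len

    def forward(self, x, training=False):
        B, L, C = x.shape
        pl, pr, out_len = self._pads(L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        win = win[:, ::self.stride]                    # (B, out, C, k)
        cols = win.transpose(0, 1, 3, 2).reshape(B * out_len,
                                                 self.kernel * C)
        y = cols @ self.w.value.reshape(self.kernel * C, self.out_ch)
        if self.b is not None:
            y += self.b.value
        self._cache = (cols, (B, L, C, pl, pr, out_len))
        return y.reshape(B, out_len, self.out_ch)

    def backward(self, grad):
        cols, (B, L, C, pl, pr, out_len) = self._cache
        g2 = grad.reshape(B * out_len, self.out_ch)
        self.w.grad += (cols.T @ g2).reshape(self.kernel, C, self.out_ch)
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        dxp = np.zeros((B, L + pl + pr, C))
        idx = self.stride * np.arange(out_len)
        for t in range(self.kernel):
            dxp[:, idx + t, :] += grad @ self.w.value[t].T
        return dxp[:, pl:pl + L, :]


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_dim)
        self.w = Param(rng.normal(0.0, std, size=(in_dim, out_dim)))
        self.b = Param(np.zeros(out_dim))
        self._x = None

    def own_params(self):
        return [self.w, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length) axes."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self._cache = None

    def own_params(self):
        return [self.gamma, self.beta]

    def own_state(self):
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def load_own_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()

    def _axes(self, x):
        return tuple(range(x.ndim - 1))

    def forward(self, x, training=False):
        axes = self._axes(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        self._cache = (xhat, std, training, x.shape)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, std, training, shape = self._cache
        axes = tuple(range(grad.ndim - 1))
        self.beta.grad += grad.sum(axis=axes)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        dxhat = grad * self.gamma.value
        if not training:
            return dxhat / std
        n = np.prod([shape[a] for a in axes])
        return (dxhat - dxhat.mean(axis=axes)
                - xhat * (dxhat * xhat).mean(axis=axes)) / std


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ArchitectureError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        self.pool = pool
        self._cache = None

    def forward(self, x, training=False):
        B, L, C = x.shape
        if L % self.pool:
            raise ArchitectureError(
                f"input length {L} not divisible by pool size {self.pool}")
        xr = x.reshape(B, L // self.pool, self.pool, C)
        arg = xr.argmax(axis=2)
        self._cache = (arg, xr.shape)
        return np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad):
        arg, shape = self._cache
        dxr = np.zeros(shape)
        np.put_along_axis(dxr, arg[:, :, None, :], grad[:, :, None, :], axis=2)
        return dxr.reshape(shape[0], shape[1] * shape[2], shape[3])


class GlobalAveragePool(Layer):
    """Collapse the time axis by averaging: (B, L, C) -> (B, C)."""

    def forward(self, x, training=False):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._L, axis=1) / self._L


class Sequential(Layer):
    def __init__(self, layers: list):
        self.layers = layers

    def sublayers(self):
        return self.layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Layer):
    """Two conv/BN/ReLU stages plus an additive skip path.

    The first convolution (and, when needed, a 1x1 skip convolution)
    carries the block's downsampling stride.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, downsample: int,
                 dropout: float = 0.0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.main = Sequential([
            Conv1D(in_ch, out_ch, kernel, stride=downsample, rng=rng),
            BatchNorm1D(out_ch),
            ReLU(),
            Dropout(dropout, rng=np.random.default_rng(rng.integers(2 ** 31))),
            Conv1D(out_ch, out_ch, kernel, stride=1, rng=rng),
            BatchNorm1D(out_ch),
        ])
        if in_ch != out_ch or downsample != 1:
            self.skip = Conv1D(in_ch, out_ch, 1, stride=downsample, rng=rng)
        else:
            self.skip = None
        self.out_relu = ReLU()

    def sublayers(self):
        subs = [self.main]
        if self.skip is not None:
            subs.append(self.skip)
        return subs

    def forward(self, x, training=False):
        m = self.main.forward(x, training=training)
        s = self.skip.forward(x, training=training) if self.skip else x
        return self.out_relu.forward(m + s, training=training)

    def backward(self, grad):
        g = self.out_relu.backward(grad)
        dx = self.main.backward(g)
        dx = dx + (self.skip.backward(g) if self.skip else g)
        return dx


class Adam:
    """Adam with the conventional moment defaults."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
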