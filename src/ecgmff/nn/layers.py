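"""Layers with explicit forward/backward passes.

Conventions: 1D activations are ``(N, C, L)``, 2D activations
``(N, C, H, W)``. ``forward(x, train=...)`` caches what ``backward`` needs;
``backward(dy)`` accumulates parameter gradients and returns the input
gradient. All arithmetic is float64 for exact correspondence with the
numerical gradient checks.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: recursive parameter discovery over attributes."""

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            out.extend(_collect(v))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x, train: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


def _collect(obj) -> list[Param]:
    if isinstance(obj, Param):
        return [obj]
    if isinstance(obj, Module):
        return obj.parameters()
    if isinstance(obj, (list, tuple)):
        out = []
        for item in obj:
            out.extend(_collect(item))
        return out
    if isinstance(obj, dict):
        out = []
        for item in obj.values():
            out.extend(_collect(item))
        return out
    return []


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Convolutions
# ---------------------------------------------------------------------------

class Conv1d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=None, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size
        self.weight = Param(
            rng.standard_normal((out_channels, in_channels, kernel_size))
            * np.sqrt(2.0 / fan_in)
        )
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, self.kernel_size, axis=2)[:, :, :: self.stride]
        out = np.einsum("nclk,ock->nol", win, self.weight.data, optimize=True)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None]
        self._cache = (xp, x.shape, win.shape[2])
        return out

    def backward(self, dy):
        xp, x_shape, lo = self._cache
        win = sliding_window_view(xp, self.kernel_size, axis=2)[:, :, :: self.stride]
        self.weight.grad += np.einsum("nclk,nol->ock", win, dy, optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        for kk in range(self.kernel_size):
            t = np.einsum("nol,oc->ncl", dy, self.weight.data[:, :, kk],
                          optimize=True)
            dxp[:, :, kk : kk + self.stride * lo : self.stride] += t
        p = self.padding
        return dxp[:, :, p : p + x_shape[2]]


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=None, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(
            rng.standard_normal(
                (out_channels, in_channels, kernel_size, kernel_size)
            )
            * np.sqrt(2.0 / fan_in)
        )
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self._cache = None

    def forward(self, x, train: bool = False):
        p, k, s = self.padding, self.kernel_size, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = np.einsum("nchwij,ocij->nohw", win, self.weight.data,
                        optimize=True)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]
        self._cache = (xp, x.shape, out.shape[2], out.shape[3])
        return out

    def backward(self, dy):
        xp, x_shape, ho, wo = self._cache
        p, k, s = self.padding, self.kernel_size, self.stride
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self.weight.grad += np.einsum("nchwij,nohw->ocij", win, dy,
                                      optimize=True)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                t = np.einsum("nohw,oc->nchw", dy, self.weight.data[:, :, ki, kj],
                              optimize=True)
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += t
        return dxp[:, :, p : p + x_shape[2], p : p + x_shape[3]]


# ---------------------------------------------------------------------------
# Normalization, activations, dropout
# ---------------------------------------------------------------------------

class BatchNorm(Module):
    """Batch normalization over all axes except the channel axis (axis 1)."""

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train: bool = False):
        axes = (0,) + tuple(range(2, x.ndim))
        sh = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) / std.reshape(sh)
        self._cache = (xhat, std, axes, sh, train)
        return self.gamma.data.reshape(sh) * xhat + self.beta.data.reshape(sh)

    def backward(self, dy):
        xhat, std, axes, sh, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.data.reshape(sh)
        if not train:
            return dy * g / std.reshape(sh)
        # per-channel element count over the reduced axes
        count = np.prod([dy.shape[a] for a in axes])
        dxhat = dy * g
        mean_dxhat = dxhat.sum(axis=axes).reshape(sh) / count
        mean_dxhat_xhat = (dxhat * xhat).sum(axis=axes).reshape(sh) / count
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) / std.reshape(sh)


def iter_modules(module: Module, cls: type):
    """Yield every sub-module of a given type reachable from a module."""
    seen = set()
    stack = [module]
    while stack:
        obj = stack.pop()
        if id(obj) in seen:
            continue
        seen.add(id(obj))
        if isinstance(obj, cls):
            yield obj
        if isinstance(obj, Module):
            stack.extend(obj.__dict__.values())
        elif isinstance(obj, (list, tuple)):
            stack.extend(obj)
        elif isinstance(obj, dict):
            stack.extend(obj.values())


def iter_batchnorms(module: Module):
    """Yield every BatchNorm reachable from a module."""
    return iter_modules(module, BatchNorm)


class ReLU(Module):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Module):
    """Inverted dropout; identity when not training or rate is 0."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train: bool = False):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

class MaxPool1d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        self.k, self.s, self.p = kernel_size, stride, padding

    def forward(self, x, train: bool = False):
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, self.k, axis=2)[:, :, :: self.s]
        self._argmax = np.argmax(win, axis=3)
        self._x_shape, self._xp_len = x.shape, xp.shape[2]
        return np.max(win, axis=3)

    def backward(self, dy):
        n, c, lo = dy.shape
        dxp = np.zeros((n, c, self._xp_len))
        ni, ci, li = np.indices((n, c, lo))
        pos = li * self.s + self._argmax
        np.add.at(dxp, (ni, ci, pos), dy)
        return dxp[:, :, self.p : self.p + self._x_shape[2]]


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        self.k, self.s, self.p = kernel_size, stride, padding

    def forward(self, x, train: bool = False):
        p = self.p
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf)
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        win = win[:, :, :: self.s, :: self.s]
        flat = win.reshape(win.shape[:4] + (self.k * self.k,))
        self._argmax = np.argmax(flat, axis=4)
        self._x_shape, self._xp_shape = x.shape, xp.shape
        return np.max(flat, axis=4)

    def backward(self, dy):
        n, c, ho, wo = dy.shape
        dxp = np.zeros(self._xp_shape)
        ni, ci, hi, wi = np.indices((n, c, ho, wo))
        ki, kj = self._argmax // self.k, self._argmax % self.k
        np.add.at(dxp, (ni, ci, hi * self.s + ki, wi * self.s + kj), dy)
        p = self.p
        return dxp[:, :, p : p + self._x_shape[2], p : p + self._x_shape[3]]


class GlobalAvgPool(Module):
    """Mean over all spatial axes: (N, C, ...) -> (N, C)."""

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, dy):
        shape = self._shape
        count = int(np.prod(shape[2:]))
        expand = dy.reshape(dy.shape + (1,) * (len(shape) - 2))
        return np.broadcast_to(expand / count, shape).copy()


# ---------------------------------------------------------------------------
# Linear, SE, losses, optimizer
# ---------------------------------------------------------------------------

class Linear(Module):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(
            rng.standard_normal((out_features, in_features))
            * np.sqrt(2.0 / in_features)
        )
        self.bias = Param(np.zeros(out_features))

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


def _sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)),
                    np.exp(z) / (1.0 + np.exp(z)))


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool to one descriptor per channel. Excitation:
    a two-layer perceptron (hidden width = the stated bottleneck) ending in a
    sigmoid, whose output rescales each channel. Works on 1D and 2D
    activations alike.
    """

    def __init__(self, channels, hidden, rng=None):
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.relu = ReLU()
        self.fc2 = Linear(hidden, channels, rng=rng)
        self._cache = None

    def channel_weights(self, x) -> np.ndarray:
        s = x.mean(axis=tuple(range(2, x.ndim)))
        return _sigmoid(self.fc2.forward(self.relu.forward(self.fc1.forward(s))))

    def forward(self, x, train: bool = False):
        spatial = tuple(range(2, x.ndim))
        s = x.mean(axis=spatial)
        z = self.fc2.forward(self.relu.forward(self.fc1.forward(s)))
        w = _sigmoid(z)
        sh = w.shape + (1,) * (x.ndim - 2)
        self._cache = (x, w, sh, spatial)
        return x * w.reshape(sh)

    def backward(self, dy):
        x, w, sh, spatial = self._cache
        dx_direct = dy * w.reshape(sh)
        dw = (dy * x).sum(axis=spatial)           # (N, C)
        dz = dw * w * (1.0 - w)
        ds = self.fc1.backward(self.relu.backward(self.fc2.backward(dz)))
        count = int(np.prod(x.shape[2:]))
        ds_full = np.broadcast_to(
            ds.reshape(sh) / count, x.shape
        )
        return dx_direct + ds_full


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch and the gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr=0.001, momentum=0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
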