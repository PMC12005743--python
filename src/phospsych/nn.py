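"""Minimal neural-network engine (numpy, explicit backprop).

Provides exactly the layer inventory the recognition models need — 2-D
convolution, max pooling, global average pooling, ReLU, batch
normalization, dense layers and residual blocks — plus softmax
cross-entropy and multimargin losses and an Adam optimizer with L2 weight
decay.  Shapes follow the NCHW convention; convolutions are evaluated via
im2col and a single matrix product.

Everything is deterministic given the seed passed to ``init``:
initialization uses He-scaled normals from one `numpy` Generator.
"""

from __future__ import annotations

import pickle
from pathlib import Path
from typing import Sequence

import numpy as np


class Layer:
    """Base layer: forward caches what backward needs."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def init(self, rng: np.random.Generator, in_shape: tuple) -> tuple:
        """Initialize parameters for the given input shape (sans batch);
        returns the output shape."""
        return in_shape

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) array pairs, matched by position."""
        return []


class Dense(Layer):
    def __init__(self, units: int):
        self.units = units

    def init(self, rng, in_shape):
        (n_in,) = in_shape
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, self.units))
        self.b = np.zeros(self.units)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        return (self.units,)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Flatten(Layer):
    def init(self, rng, in_shape):
        self._shape = in_shape
        return (int(np.prod(in_shape)),)

    def forward(self, x, train=False):
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], *self._shape)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, out_h, out_w, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    out_h = (h - k) // stride + 1
    out_w = (w - k) // stride + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, out_h, out_w, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, out_h, out_w, c * k * k)


class Conv2d(Layer):
    """Square-kernel 2-D convolution (cross-correlation) with zero padding."""

    def __init__(self, filters: int, kernel: int, stride: int = 1, pad: int = 0):
        self.filters, self.kernel, self.stride, self.pad = filters, kernel, stride, pad

    def init(self, rng, in_shape):
        c, h, w = in_shape
        fan_in = c * self.kernel**2
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (self.filters, c, self.kernel, self.kernel))
        self.b = np.zeros(self.filters)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        out_h = (h + 2 * self.pad - self.kernel) // self.stride + 1
        out_w = (w + 2 * self.pad - self.kernel) // self.stride + 1
        return (self.filters, out_h, out_w)

    def forward(self, x, train=False):
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad,) * 2, (self.pad,) * 2))
        self._xp_shape = x.shape
        cols = _im2col(x, self.kernel, self.stride)  # (N, oh, ow, C*k*k)
        self._cols = cols
        out = cols @ self.w.reshape(self.filters, -1).T + self.b
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, f, oh, ow = grad.shape
        g = grad.transpose(0, 2, 3, 1).reshape(-1, f)  # (N*oh*ow, F)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.gw[...] = (g.T @ cols).reshape(self.w.shape)
        self.gb[...] = g.sum(0)

        gcols = (g @ self.w.reshape(f, -1)).reshape(n, oh, ow, -1)
        # scatter patch gradients back (col2im)
        _, c, hp, wp = self._xp_shape
        k, s = self.kernel, self.stride
        gx = np.zeros(self._xp_shape)
        gcols = gcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + oh * s : s, j : j + ow * s : s] += gcols[:, :, :, :, i, j]
        if self.pad:
            gx = gx[:, :, self.pad : hp - self.pad, self.pad : wp - self.pad]
        return gx

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class MaxPool2d(Layer):
    """Non-overlapping max pooling; pads with -inf if the side is indivisible."""

    def __init__(self, k: int):
        self.k = k

    def init(self, rng, in_shape):
        c, h, w = in_shape
        return (c, -(-h // self.k), -(-w // self.k))

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        k = self.k
        ph, pw = -(-h // k) * k, -(-w // k) * k
        if (ph, pw) != (h, w):
            x = np.pad(x, ((0, 0), (0, 0), (0, ph - h), (0, pw - w)), constant_values=-np.inf)
        self._in_hw = (h, w)
        xr = x.reshape(n, c, ph // k, k, pw // k, k)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, grad):
        n, c, oh, ow = grad.shape
        k = self.k
        g = self._mask * grad[:, :, :, None, :, None]
        g = g.reshape(n, c, oh * k, ow * k)
        h, w = self._in_hw
        return g[:, :, :h, :w]


class GlobalAvgPool(Layer):
    def init(self, rng, in_shape):
        c, h, w = in_shape
        self._hw = (h, w)
        return (c,)

    def forward(self, x, train=False):
        self._n_px = x.shape[2] * x.shape[3]
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        h, w = self._hw
        return np.broadcast_to(grad[:, :, None, None], grad.shape + (h, w)) / self._n_px


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5):
        self.momentum, self.eps = momentum, eps

    def init(self, rng, in_shape):
        c = in_shape[0]
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.run_mean = np.zeros(c)
        self.run_var = np.ones(c)
        return in_shape

    @staticmethod
    def _stats_axes(x):
        return (0, 2, 3) if x.ndim == 4 else (0,)

    def _shape(self, v, ndim):
        return v.reshape(1, -1, 1, 1) if ndim == 4 else v

    def forward(self, x, train=False):
        ax = self._stats_axes(x)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        sh = lambda v: self._shape(v, x.ndim)
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - sh(mean)) / sh(self._std)
        self._m = x.size // x.shape[1]
        return sh(self.gamma) * self._xhat + sh(self.beta)

    def backward(self, grad):
        ax = self._stats_axes(grad)
        sh = lambda v: self._shape(v, grad.ndim)
        self.ggamma[...] = (grad * self._xhat).sum(axis=ax)
        self.gbeta[...] = grad.sum(axis=ax)
        m = self._m
        gxhat = grad * sh(self.gamma)
        return (
            gxhat - sh(gxhat.sum(axis=ax)) / m - self._xhat * sh((gxhat * self._xhat).sum(axis=ax)) / m
        ) / sh(self._std)

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class Residual(Layer):
    """y = f(x) + g(x) where g is identity or a 1x1-conv shortcut."""

    def __init__(self, body: "Sequential", shortcut: "Sequential | None" = None):
        self.body = body
        self.shortcut = shortcut

    def init(self, rng, in_shape):
        out = self.body.init_shapes(rng, in_shape)
        if self.shortcut is not None:
            short = self.shortcut.init_shapes(rng, in_shape)
            if short != out:
                raise ValueError(f"shortcut shape {short} != body shape {out}")
        elif out != in_shape:
            raise ValueError(f"identity residual needs matching shapes, {in_shape} -> {out}")
        return out

    def forward(self, x, train=False):
        y = self.body.forward(x, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return y + s

    def backward(self, grad):
        gx = self.body.backward(grad)
        gs = grad if self.shortcut is None else self.shortcut.backward(grad)
        return gx + gs

    def params(self):
        out = self.body.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def init_shapes(self, rng, in_shape):
        shape = in_shape
        for layer in self.layers:
            shape = layer.init(rng, shape)
        return shape

    init = init_shapes

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    # -- serialization -------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(state):
            raise ValueError("state does not match architecture")
        for (p, _), s in zip(own, state):
            p[...] = s

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        bn = [
            (l.run_mean.copy(), l.run_var.copy())
            for l in self._walk()
            if isinstance(l, BatchNorm2d)
        ]
        with open(path, "wb") as f:
            pickle.dump({"state": self.state(), "bn": bn, "meta": meta or {}}, f)

    def load(self, path: str | Path) -> dict:
        with open(path, "rb") as f:
            blob = pickle.load(f)
        self.load_state(blob["state"])
        bns = [l for l in self._walk() if isinstance(l, BatchNorm2d)]
        for l, (m, v) in zip(bns, blob["bn"]):
            l.run_mean, l.run_var = m.copy(), v.copy()
        return blob["meta"]

    def _walk(self):
        for l in self.layers:
            if isinstance(l, Sequential):
                yield from l._walk()
            elif isinstance(l, Residual):
                yield from l.body._walk()
                if l.shortcut is not None:
                    yield from l.shortcut._walk()
            else:
                yield l


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = softmax(logits)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


def multimargin(logits: np.ndarray, y: np.ndarray, margin: float = 1.0) -> tuple[float, np.ndarray]:
    """Multiclass margin (hinge) loss, p=1, averaged over classes and batch.

    loss_i = mean_j max(0, margin - x_y + x_j) over j != y.
    """
    n, c = logits.shape
    correct = logits[np.arange(n), y][:, None]
    viol = np.maximum(0.0, margin - correct + logits)
    viol[np.arange(n), y] = 0.0
    loss = viol.sum() / (n * c)
    grad = (viol > 0).astype(float)
    grad[np.arange(n), y] = -grad.sum(axis=1)
    return loss, grad / (n * c)


def mse(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


LOSSES = {"cel": cross_entropy, "mml": multimargin, "mse": mse}


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for (p, g), m, v in zip(self.params, self.m, self.v):
            g = g + self.wd * p
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
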