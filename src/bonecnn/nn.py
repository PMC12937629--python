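"""Minimal NumPy neural-network layers with exact backward passes.

This module provides exactly the primitives the radiograph classifier
needs — standard and depthwise 2-D convolutions, batch normalisation,
ReLU, dropout, global average pooling, fully connected layers — plus the
Adam optimiser and a softmax cross-entropy loss computed from logits.

Conventions
-----------
* Tensors are ``float32`` NumPy arrays in NCHW layout (batch, channel,
  height, width); fully connected layers take NC.
* Every layer exposes ``forward(x, train)`` and ``backward(dy)``;
  ``backward`` must be called with the gradient of the loss w.r.t. the
  layer's last forward output and returns the gradient w.r.t. its input.
* Parameters are :class:`Param` objects; gradients accumulate into
  ``param.grad`` during ``backward`` and are consumed by the optimiser.
* Convolutions use "same"-style padding ``k // 2`` so spatial size maps
  ``H -> ceil(H / stride)`` for the strides used here.

Gradients are verified against central finite differences in the test
suite, which is the correctness contract for everything below.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array together with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base class: a named, possibly parameterised, differentiable op."""

    name: str = ""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col / col2im helpers (k x k loop keeps both fully vectorised in N,C,H,W)
# ---------------------------------------------------------------------------

def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*k*k, Hout*Wout) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * k * k, ho * wo)


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to an image."""
    n, c, h, w = x_shape
    ho, wo = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Conv2d(Layer):
    """Standard 2-D convolution, padding k//2, optional bias.

    Weight layout ``(C_out, C_in, k, k)``; initialised He-normal from the
    supplied generator so builds are reproducible.
    """

    def __init__(
        self,
        name: str,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = k // 2
        fan_in = c_in * k * k
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.w = Param(f"{name}.weight", w)
        self.b = Param(f"{name}.bias", np.zeros(c_out)) if bias else None
        self._cache: tuple | None = None
        self.last_out_hw: tuple[int, int] | None = None  # recorded each forward

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (_out_size(h, self.k, self.stride, self.pad),
                _out_size(w, self.k, self.stride, self.pad))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n = x.shape[0]
        ho, wo = self.out_hw(x.shape[2], x.shape[3])
        cols = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.w.value.reshape(self.c_out, -1)
        y = np.matmul(wmat[None], cols).reshape(n, self.c_out, ho, wo)
        if self.b is not None:
            y += self.b.value[None, :, None, None]
        self._cache = (x.shape, cols)
        self.last_out_hw = (ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n = dy.shape[0]
        dyf = dy.reshape(n, self.c_out, -1)
        self.w.grad += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2, 3))
        wmat = self.w.value.reshape(self.c_out, -1)
        dcols = np.matmul(wmat.T[None], dyf)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class DepthwiseConv2d(Layer):
    """Per-channel spatial convolution (channel multiplier 1)."""

    def __init__(
        self,
        name: str,
        channels: int,
        k: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.channels, self.k, self.stride = channels, k, stride
        self.pad = k // 2
        w = rng.normal(0.0, math.sqrt(2.0 / (k * k)), size=(channels, k, k))
        self.w = Param(f"{name}.weight", w)
        self._cache: tuple | None = None
        self.last_out_hw: tuple[int, int] | None = None

    def params(self) -> list[Param]:
        return [self.w]

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        return (_out_size(h, self.k, self.stride, self.pad),
                _out_size(w, self.k, self.stride, self.pad))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = self.out_hw(h, w)
        # patches: (N, C, k, k, Ho, Wo)
        patches = _im2col(x, self.k, self.stride, self.pad).reshape(n, c, self.k, self.k, ho, wo)
        y = np.einsum("ncklhw,ckl->nchw", patches, self.w.value, optimize=True)
        self._cache = (x.shape, patches)
        self.last_out_hw = (ho, wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, patches = self._cache
        self.w.grad += np.einsum("ncklhw,nchw->ckl", patches, dy, optimize=True)
        dpatches = np.einsum("ckl,nchw->ncklhw", self.w.value, dy, optimize=True)
        n, c = x_shape[0], x_shape[1]
        dcols = dpatches.reshape(n, c * self.k * self.k, -1)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Batch normalisation over (N, H, W) with running statistics."""

    def __init__(self, name: str, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.name = name
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(channels))
        self.beta = Param(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = x.shape[0] * x.shape[2] * x.shape[3]
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mean).astype(DTYPE)
            unbiased = var * m / max(m - 1, 1)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * unbiased).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv_std, train)
        return y.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return (dy * g * inv_std[None, :, None, None]).astype(DTYPE)
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (dxhat - s1 / m - xhat * s2 / m) * inv_std[None, :, None, None]
        return dx.astype(DTYPE)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        self.name = name
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, name: str, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.name = name
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def reseed(self, rng: np.random.Generator) -> None:
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def __init__(self, name: str = "gap"):
        self.name = name
        self._hw: tuple[int, int] | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._hw = x.shape[2:]
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        return np.broadcast_to(dy[:, :, None, None], dy.shape + (h, w)).astype(dy.dtype) / (h * w)


class Linear(Layer):
    def __init__(self, name: str, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.name = name
        self.n_in, self.n_out = n_in, n_out
        w = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.w = Param(f"{name}.weight", w)
        self.b = Param(f"{name}.bias", np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class Sequential(Layer):
    def __init__(self, name: str, layers: Sequence[Layer]):
        self.name = name
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


# ---------------------------------------------------------------------------
# Loss and optimiser
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy from logits.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the
    mean loss w.r.t. the logits (softmax minus one-hot, divided by n).
    """
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), labels]))
    p = softmax(logits)
    p[np.arange(n), labels] -= 1.0
    return loss, (p / n).astype(DTYPE)


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(
        self,
        params: Iterable[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
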