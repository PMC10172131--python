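"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations needed by the contrastive encoders and the
InfoNCE objective: dense and 1-D convolutional layers, GELU, row
normalization, similarity matrices, log-sum-exp, and a handful of reductions.
All computation is float64. Gradients are accumulated by a topological sweep
over the recorded graph; `detach`-style constants (for example the row-max
shift in the stabilized loss) are handled by simply using raw numpy values.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


class Tensor:
    """A numpy array with an optional gradient and a backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul_scalar(_as_tensor(other), -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _make(data, parents, backward, requires_grad):
    out = Tensor(data, requires_grad=requires_grad)
    if requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise and linear ops -------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs(a, b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), backward, req)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs(a, b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), backward, req)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s)

    return _make(a.data * s, (a,), backward, a.requires_grad)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs(a, b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward, req)


def matmul_t(a: Tensor, b: Tensor) -> Tensor:
    """a @ b.T for 2-D tensors (similarity matrices)."""
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs(a, b)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data)
        if b.requires_grad:
            b._accumulate(g.T @ a.data)

    return _make(a.data @ b.data.T, (a, b), backward, req)


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear-unit: x * Phi(x)."""
    x = _as_tensor(x)
    cdf = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))

    def backward(g):
        if x.requires_grad:
            pdf = _INV_SQRT2PI * np.exp(-0.5 * x.data * x.data)
            x._accumulate(g * (cdf + x.data * pdf))

    return _make(x.data * cdf, (x,), backward, x.requires_grad)


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.exp(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data)

    return _make(out_data, (x,), backward, x.requires_grad)


def clamp_max(x: Tensor, hi: float) -> Tensor:
    """min(x, hi); gradient is zero where the clamp is active."""
    x = _as_tensor(x)
    mask = x.data < hi

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return _make(np.minimum(x.data, hi), (x,), backward, x.requires_grad)


def sum_all(x: Tensor) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g, x.data.shape))

    return _make(x.data.sum(), (x,), backward, x.requires_grad)


def mean_all(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(g / n, x.data.shape))

    return _make(x.data.mean(), (x,), backward, x.requires_grad)


def row_sum(x: Tensor, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        if x.requires_grad:
            gg = g if keepdims else g[:, None]
            x._accumulate(np.broadcast_to(gg, x.data.shape))

    return _make(x.data.sum(axis=1, keepdims=keepdims), (x,), backward,
                 x.requires_grad)


def row_dot(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise dot products of two [n x E] tensors -> [n]."""
    return row_sum(mul(a, b))


def logsumexp_rows(x: Tensor) -> Tensor:
    """log(sum(exp(x), axis=1)) with an internal detached row-max shift.

    The shift cancels analytically, so the value equals the naive formula in
    exact arithmetic while staying finite for large similarities.
    """
    x = _as_tensor(x)
    c = x.data.max(axis=1, keepdims=True)
    ex = np.exp(x.data - c)
    s = ex.sum(axis=1, keepdims=True)
    out_data = (np.log(s) + c)[:, 0]

    def backward(g):
        if x.requires_grad:
            x._accumulate(g[:, None] * (ex / s))

    return _make(out_data, (x,), backward, x.requires_grad)


def normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Project each row onto the unit hypersphere."""
    x = _as_tensor(x)
    norm = np.sqrt((x.data * x.data).sum(axis=1, keepdims=True))
    norm = np.maximum(norm, eps)
    y = x.data / norm

    def backward(g):
        if x.requires_grad:
            proj = (g * y).sum(axis=1, keepdims=True)
            x._accumulate((g - y * proj) / norm)

    return _make(y, (x,), backward, x.requires_grad)


def slice_cols(x: Tensor, start: int, stop: int) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        if x.requires_grad:
            gg = np.zeros_like(x.data)
            gg[:, start:stop] = g
            x._accumulate(gg)

    return _make(x.data[:, start:stop], (x,), backward, x.requires_grad)


def concat_rows(tensors: list[Tensor]) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    tensors = [_as_tensor(t) for t in tensors]
    req = _needs(*tensors)
    sizes = [t.data.shape[0] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[a:b])

    return _make(np.concatenate([t.data for t in tensors], axis=0),
                 tensors, backward, req)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor (scatter-add on the way back)."""
    x = _as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)

    def backward(g):
        if x.requires_grad:
            gg = np.zeros_like(x.data)
            np.add.at(gg, idx, g)
            x._accumulate(gg)

    return _make(x.data[idx], (x,), backward, x.requires_grad)


# -- temporal ops (N, C, L layout) ----------------------------------------

def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Sliding windows over the last axis: (N, C, L) -> (N, C, Lout, k)."""
    n, c, l = x.shape
    lout = (l - k) // stride + 1
    s0, s1, s2 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(n, c, lout, k), strides=(s0, s1, s2 * stride, s2),
        writeable=False)


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Valid 1-D convolution (cross-correlation): x (N,C,L), w (O,C,K), b (O)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    req = _needs(x, w, b)
    k = w.data.shape[2]
    win = _windows(x.data, k, stride)
    out_data = np.einsum("nclk,ock->nol", win, w.data, optimize=True)
    out_data += b.data[None, :, None]

    def backward(g):
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2)))
        if w.requires_grad:
            w._accumulate(np.einsum("nclk,nol->ock", win, g, optimize=True))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            lout = g.shape[2]
            for j in range(k):
                # each kernel tap scatters onto a strided slice of the input
                gx[:, :, j:j + stride * lout:stride] += np.einsum(
                    "nol,oc->ncl", g, w.data[:, :, j], optimize=True)
            x._accumulate(gx)

    return _make(out_data, (x, w, b), backward, req)


def avgpool2(x: Tensor) -> Tensor:
    """Fixed 2x temporal downsample: mean over non-overlapping pairs."""
    x = _as_tensor(x)
    n, c, l = x.data.shape
    lo = l // 2
    trimmed = x.data[:, :, :2 * lo]
    out_data = trimmed.reshape(n, c, lo, 2).mean(axis=3)

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, :2 * lo] = np.repeat(g, 2, axis=2) * 0.5
            x._accumulate(gx)

    return _make(out_data, (x,), backward, x.requires_grad)


def slice_time(x: Tensor, start: int, stop: int) -> Tensor:
    """Slice the last (time) axis of an (N, C, L) tensor."""
    x = _as_tensor(x)

    def backward(g):
        if x.requires_grad:
            gg = np.zeros_like(x.data)
            gg[:, :, start:stop] = g
            x._accumulate(gg)

    return _make(x.data[:, :, start:stop], (x,), backward, x.requires_grad)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate (N, C, L) tensors along the channel axis."""
    a, b = _as_tensor(a), _as_tensor(b)
    req = _needs(a, b)
    ca = a.data.shape[1]

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[:, :ca])
        if b.requires_grad:
            b._accumulate(g[:, ca:])

    return _make(np.concatenate([a.data, b.data], axis=1), (a, b),
                 backward, req)


# -- optimizers ------------------------------------------------------------

class Adam:
    """Adam with the usual (beta1, beta2, eps) = (0.9, 0.999, 1e-8) defaults."""

    def __init__(self, params: list[Tensor], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
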