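"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the secondary-structure network needs:
broadcasting arithmetic, (batched) matmul, softmax / log-softmax, the usual
pointwise nonlinearities, 2D convolution with dilation, bucket-table lookup,
diagonal extraction, concatenation and axis permutation.  Gradients are
accumulated by topological-order backward passes; every op is checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit

# float32 keeps the conv-heavy training loop fast; tests that finite-difference
# the gradients switch this to float64 for headroom.
DEFAULT_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DEFAULT_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    # ---- graph construction helpers -------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # ---- operators -------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(_wrap(other), -self)

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return permute(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---- arithmetic -----------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    data = a.data**p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    """Matrix product; batched when operands share leading dimensions."""
    a, b = _wrap(a), _wrap(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


# ---- shape ops ------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def permute(a, axes) -> Tensor:
    a = _wrap(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    if not axes:
        axes = tuple(reversed(range(a.ndim)))
    inv = np.argsort(axes)
    data = np.transpose(a.data, axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return _make(data, (a,), backward)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


# ---- pointwise nonlinearities ---------------------------------------------


def exp(a) -> Tensor:
    a = _wrap(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0)

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    data = expit(a.data)

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = _wrap(a)
    x = a.data
    phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
    data = x * phi

    def backward(g):
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        a._accumulate(g * (phi + x * pdf))

    return _make(data.astype(a.data.dtype), (a,), backward)


def softmax(a, axis=-1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accumulate(data * (g - dot))

    return _make(data, (a,), backward)


def log_softmax(a, axis=-1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse

    def backward(g):
        p = np.exp(data)
        a._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return _make(data, (a,), backward)


# ---- structured ops -------------------------------------------------------


def lookup(table, idx) -> Tensor:
    """Row lookup `table[idx]` with scatter-add gradient (RPE bias table)."""
    table = _wrap(table)
    idx = np.asarray(idx)
    data = table.data[idx]

    def backward(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx, g)
        table._accumulate(gt)

    return _make(data, (table,), backward)


def take_diagonal(a) -> Tensor:
    """(C, P, P) pairwise feature -> (P, C) per-position descriptor."""
    a = _wrap(a)
    C, P, P2 = a.data.shape
    if P != P2:
        raise ValueError(f"pairwise feature must be spatially square, got {P}x{P2}")
    rng = np.arange(P)
    data = a.data[:, rng, rng].T  # (P, C)

    def backward(g):
        ga = np.zeros_like(a.data)
        ga[:, rng, rng] = g.T
        a._accumulate(ga)

    return _make(data, (a,), backward)


def conv2d(x, w, b, padding: int, dilation: int = 1) -> Tensor:
    """2D convolution on a single (C_in, P, P) map via im2col.

    Output spatial size is P + 2*padding - dilation*(k-1); shape-preserving
    when padding == dilation*(k-1)/2.
    """
    x, w, b = _wrap(x), _wrap(w), _wrap(b)
    C, P, _ = x.data.shape
    Cout, Cin, k, _ = w.data.shape
    if Cin != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Cin}")
    Q = P + 2 * padding - dilation * (k - 1)
    if Q < 1:
        raise ValueError("conv2d output would be empty; increase padding")
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding)))
    s = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp,
        shape=(C, k, k, Q, Q),
        strides=(s[0], s[1] * dilation, s[2] * dilation, s[1], s[2]),
    )
    cols = patches.reshape(C * k * k, Q * Q)  # copies
    wmat = w.data.reshape(Cout, C * k * k)
    data = (wmat @ cols + b.data[:, None]).reshape(Cout, Q, Q)

    def backward(g):
        gmat = g.reshape(Cout, Q * Q)
        if b.requires_grad:
            b._accumulate(gmat.sum(axis=1))
        if w.requires_grad:
            w._accumulate((gmat @ cols.T).reshape(w.data.shape))
        if x.requires_grad:
            gcols = (wmat.T @ gmat).reshape(C, k, k, Q, Q)
            gxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    gxp[:, ki * dilation:ki * dilation + Q,
                        kj * dilation:kj * dilation + Q] += gcols[:, ki, kj]
            if padding:
                gxp = gxp[:, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return _make(data, (x, w, b), backward)


# ---- parameters -----------------------------------------------------------


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: recursive parameter discovery and zeroing."""

    def parameters(self) -> list:
        out = []
        for v in vars(self).values():
            out.extend(_collect(v))
        return out

    def named_parameters(self, prefix: str = "") -> list:
        out = []
        for name, v in vars(self).items():
            out.extend(_collect_named(v, f"{prefix}{name}"))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(v):
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_named(v, name):
    if isinstance(v, Parameter):
        return [(name, v)]
    if isinstance(v, Module):
        return v.named_parameters(prefix=name + ".")
    if isinstance(v, (list, tuple)):
        out = []
        for i, item in enumerate(v):
            out.extend(_collect_named(item, f"{name}.{i}"))
        return out
    return []
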