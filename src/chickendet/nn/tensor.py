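"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every op builds a closure that
propagates cotangents to its inputs.  Only the primitives needed by the
detection stack are provided (elementwise math, reductions, reshaping,
matmul, convolution/pooling live in :mod:`chickendet.nn.functional`).
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled", "as_tensor"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # --------------------------------------------------------------- wrappers
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes or None)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def sigmoid(self):
        return sigmoid(self)

    def clamp(self, lo=None, hi=None):
        return clamp(self, lo, hi)


class Parameter(Tensor):
    """A trainable tensor (counted by ``Module.parameters``)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, prev: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in prev if isinstance(p, Tensor))
    if is_grad_enabled() and any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


# ------------------------------------------------------------------ primitives

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = _expit(a.data)

    def backward(g):
        a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def silu(a) -> Tensor:
    a = as_tensor(a)
    s = _expit(a.data)
    data = a.data * s

    def backward(g):
        a._accumulate(g * (s + a.data * s * (1.0 - s)))

    return _make(data, (a,), backward)


def atan(a) -> Tensor:
    a = as_tensor(a)
    data = np.arctan(a.data)

    def backward(g):
        a._accumulate(g / (1.0 + a.data ** 2))

    return _make(data, (a,), backward)


def bce_with_logits(logits, targets) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    x = as_tensor(logits)
    t = np.asarray(targets, dtype=np.float32)
    data = np.maximum(x.data, 0) - x.data * t + np.log1p(np.exp(-np.abs(x.data)))
    sig = _expit(x.data)

    def backward(g):
        x._accumulate(g * (sig - t))

    return _make(data, (x,), backward)


def clamp(a, lo=None, hi=None) -> Tensor:
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= a.data >= lo
    if hi is not None:
        mask *= a.data <= hi

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = np.maximum(a.data, b.data)
    amask = (a.data >= b.data).astype(np.float32)

    def backward(g):
        a._accumulate(_unbroadcast(g * amask, a.shape))
        b._accumulate(_unbroadcast(g * (1.0 - amask), b.shape))

    return _make(data, (a, b), backward)


def minimum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = np.minimum(a.data, b.data)
    amask = (a.data <= b.data).astype(np.float32)

    def backward(g):
        a._accumulate(_unbroadcast(g * amask, a.shape))
        b._accumulate(_unbroadcast(g * (1.0 - amask), b.shape))

    return _make(data, (a, b), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(ax % a.ndim for ax in axes)
            shape = [1 if i in axes else s for i, s in enumerate(a.shape)]
            g = g.reshape(shape)
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax % a.ndim] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a, axes=None) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = None if axes is None else tuple(np.argsort(axes))

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    data = a.data[idx]

    def backward(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accumulate(full)

    return _make(data, (a,), backward)


def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, ts, backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(data, (a, b), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return _make(s, (a,), backward)


def where_mask(mask: np.ndarray, a, b) -> Tensor:
    """Select a where boolean `mask` (constant) holds, else b."""
    a, b = as_tensor(a), as_tensor(b)
    m = np.asarray(mask, dtype=bool)
    data = np.where(m, a.data, b.data)

    def backward(g):
        a._accumulate(_unbroadcast(np.where(m, g, 0.0), a.shape))
        b._accumulate(_unbroadcast(np.where(m, 0.0, g), b.shape))

    return _make(data, (a, b), backward)
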