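"""Reverse-mode automatic differentiation over NumPy arrays.

A small tape-based engine in the micrograd tradition, extended to full
tensors: every operation records its inputs and a closure computing the
vector-Jacobian product. ``Tensor.backward`` walks the tape in reverse
topological order and accumulates gradients into every tensor that
requires them. Constants (``requires_grad=False`` and no differentiable
parents) never enter the tape, so detaching a tensor *is* the
stop-gradient operator used throughout the models.

All data is float64. The engine implements exactly the operations the
models need (broadcast arithmetic, matmul incl. batched, reductions,
softmax, gather/scatter, sparse-dense matmul) — it is not a general
framework.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "exp",
    "gather_rows",
    "log",
    "matmul",
    "maximum_",
    "relu",
    "leaky_relu",
    "softmax",
    "spmm",
    "sqrt",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # Make ndarray <op> Tensor defer to Tensor's reflected operators
    # instead of NumPy broadcasting over a Python object.
    __array_priority__ = 1000
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.ravel()[0])

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph management ----------------------------------------------
    def detach(self) -> "Tensor":
        """Stop-gradient: a constant view of this tensor's values."""
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64) if self.grad is None \
            else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(as_tensor(other), self)

    # -- shaped views ----------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g, t=self, old=old):
            _accumulate(t, g.reshape(old))

        return _build(out_data, (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)

        def backward(g, t=self, inv=inv):
            _accumulate(t, g.transpose(inv))

        return _build(out_data, (self,), backward)

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g, t=self, axis=axis, keepdims=keepdims, shape=shape):
            if axis is None:
                ge = np.broadcast_to(g, shape)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                ge = np.broadcast_to(g, shape)
            _accumulate(t, ge)

        return _build(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        """Maximum along an axis; gradient flows to the argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)

        def backward(g, t=self, axis=axis, keepdims=keepdims, idx=idx):
            if keepdims:
                g = np.squeeze(g, axis=axis)
            gx = np.zeros_like(t.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis)
            _accumulate(t, gx)

        return _build(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = g.copy() if t.grad is None else t.grad + g


def _build(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- elementwise arithmetic ---------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g, a=a, b=b):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _build(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g, a=a, b=b):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _build(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g, a=a, b=b):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _build(out_data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g, a=a, p=p):
        with np.errstate(divide="ignore", invalid="ignore"):
            grad = p * a.data ** (p - 1.0)
        grad = np.where(np.isfinite(grad), grad, 0.0)
        _accumulate(a, g * grad)

    return _build(out_data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g, a=a, out_data=out_data):
        _accumulate(a, g * out_data)

    return _build(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g, a=a):
        _accumulate(a, g / a.data)

    return _build(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g, a=a, out_data=out_data):
        _accumulate(a, g * (1.0 - out_data ** 2))

    return _build(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g, a=a):
        _accumulate(a, g * (a.data > 0.0))

    return _build(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    out_data = np.where(a.data > 0.0, a.data, slope * a.data)

    def backward(g, a=a, slope=slope):
        _accumulate(a, g * np.where(a.data > 0.0, 1.0, slope))

    return _build(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.where(a.data >= 0,
                        1.0 / (1.0 + np.exp(-np.abs(a.data))),
                        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))

    def backward(g, a=a, out_data=out_data):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return _build(out_data, (a,), backward)


def maximum_(a, b) -> Tensor:
    """Elementwise maximum; ties send the gradient to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data
    out_data = np.where(take_a, a.data, b.data)

    def backward(g, a=a, b=b, take_a=take_a):
        _accumulate(a, _unbroadcast(g * take_a, a.data.shape))
        _accumulate(b, _unbroadcast(g * ~take_a, b.data.shape))

    return _build(out_data, (a, b), backward)


# -- linear algebra ------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g, a=a, b=b):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _accumulate(a, _unbroadcast(ga, a.data.shape))
        _accumulate(b, _unbroadcast(gb, b.data.shape))

    return _build(out_data, (a, b), backward)


def spmm(S: sp.spmatrix, x) -> Tensor:
    """Sparse constant matrix times dense tensor, ``S @ x``."""
    x = as_tensor(x)
    out_data = S @ x.data

    def backward(g, x=x, St=S.T.tocsr()):
        _accumulate(x, St @ g)

    return _build(np.asarray(out_data), (x,), backward)


def gather_rows(x, idx) -> Tensor:
    """Select rows ``x[idx]``; backward scatter-adds into the source."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def backward(g, x=x, idx=idx):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        _accumulate(x, gx)

    return _build(out_data, (x,), backward)


def concat(tensors: Iterable, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(sl)])

    return _build(out_data, tuple(tensors), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g, a=a, out_data=out_data, axis=axis):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accumulate(a, out_data * (g - dot))

    return _build(out_data, (a,), backward)
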