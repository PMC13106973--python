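"""Minimal reverse-mode automatic differentiation over numpy arrays.

The attention network and its losses need gradients of scalar losses with
respect to a few hundred parameter arrays on problem sizes of tens of
residues, so the engine is deliberately small: a ``Tensor`` wrapping an
ndarray, a closed set of differentiable primitives with full numpy
broadcasting, and topological-order backpropagation.  Everything is
dtype-preserving; training uses float32, equivalence tests use float64.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    """A differentiable array node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- bookkeeping ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        other = astensor(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.shape)
                )

        return Tensor(self.data / other.data, _parents=(self, other), _backward=bw)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g):
            self._accum(g * e * self.data ** (e - 1.0))

        return Tensor(self.data**e, _parents=(self,), _backward=bw)

    def __matmul__(self, other):
        other = astensor(other)
        out = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.multiply.outer(g, other.data) if g.ndim else g * other.data
                else:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    if self.data.ndim == 1:
                        ga = ga.sum(axis=tuple(range(ga.ndim - 1)))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.multiply.outer(self.data, g) if g.ndim else self.data * g
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    if other.data.ndim == 1:
                        gb = gb.sum(axis=tuple(range(gb.ndim - 1)))
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor(out, _parents=(self, other), _backward=bw)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))

        return Tensor(self.data.reshape(shape), _parents=(self,), _backward=bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            self._accum(np.transpose(g, inv))

        return Tensor(np.transpose(self.data, axes), _parents=(self,), _backward=bw)

    def swapaxes(self, a: int, b: int):
        def bw(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.data, a, b), _parents=(self,), _backward=bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _backward=bw,
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise ----------------------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)

        return Tensor(out, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            self._accum(g / (2.0 * out))

        return Tensor(out, _parents=(self,), _backward=bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out**2))

        return Tensor(out, _parents=(self,), _backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * out * (1.0 - out))

        return Tensor(out, _parents=(self,), _backward=bw)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


# -- composite helpers ---------------------------------------------------

def concat(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def stack(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]

    def bw(g):
        pieces = np.moveaxis(g, axis, 0)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def where(cond, a, b) -> Tensor:
    cond = np.asarray(cond)
    a, b = astensor(a), astensor(b)

    def bw(g):
        if a.requires_grad:
            a._accum(_unbroadcast(np.where(cond, g, 0.0), a.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(np.where(cond, 0.0, g), b.shape))

    return Tensor(np.where(cond, a.data, b.data), _parents=(a, b), _backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shifting by a detached max leaves both value and gradient exact
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def clamp_min(x: Tensor, lo: float) -> Tensor:
    return where(x.data < lo, astensor(np.asarray(lo, dtype=x.dtype)), x)


def clamp_max(x: Tensor, hi: float) -> Tensor:
    return where(x.data > hi, astensor(np.asarray(hi, dtype=x.dtype)), x)


def norm(x: Tensor, axis: int = -1, keepdims: bool = False, eps: float = 0.0) -> Tensor:
    return ((x * x).sum(axis=axis, keepdims=keepdims) + eps).sqrt()
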