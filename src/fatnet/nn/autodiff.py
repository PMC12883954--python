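"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is intentionally small: a :class:`Tensor` wraps an ndarray,
records the operations that produced it, and :meth:`Tensor.backward`
runs the reverse sweep in topological order.  Only the operations the
network architectures in this package need are implemented, several of
them as fused primitives (conv1d, LSTM, layer/batch norm) for speed.

All gradients are checked against central finite differences in the
test suite; the engine supports float64 so those checks are exact to
roundoff.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gelu", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_borrowed")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self._grad_borrowed = False

    # -- infrastructure ------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray) -> None:
        # First contribution borrows the incoming array (it may be a
        # view shared with a sibling, so it is never mutated in place);
        # a second contribution allocates an owned sum.
        if self.grad is None:
            self.grad = grad
            self._grad_borrowed = True
        elif self._grad_borrowed:
            self.grad = self.grad + grad
            self._grad_borrowed = False
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs contain O(T) LSTM-free nodes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req, parents=[p for p in parents if p.requires_grad],
                      backward=backward if req else None)

    # -- elementwise arithmetic ---------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), bwd)

    # -- reductions / shaping -----------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        return self._make(out_data, (self,), bwd)

    def swapaxes(self, a: int, b: int):
        out_data = self.data.swapaxes(a, b)

        def bwd(g):
            self._accum(g.swapaxes(a, b))

        return self._make(out_data, (self,), bwd)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return self._make(out_data, (self,), bwd)

    # -- linear algebra ------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, other.data.swapaxes(-1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(self.data.swapaxes(-1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = _sigmoid(self.data)

        def bwd(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def bwd(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), bwd)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) GELU."""
    from scipy.special import erf

    xd = x.data
    phi = 0.5 * (1.0 + erf(xd * _INV_SQRT2))
    out_data = xd * phi

    def bwd(g):
        pdf = np.exp(-0.5 * xd ** 2) * _INV_SQRT2PI
        x._accum(g * (phi + xd * pdf))

    return x._make(out_data, (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    xd = x.data
    m = xd.max(axis=axis, keepdims=True)
    e = np.exp(xd - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return x._make(out_data, (x,), bwd)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, requires_grad=req,
                  parents=[t for t in tensors if t.requires_grad],
                  backward=bwd if req else None)
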