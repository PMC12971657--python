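"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: every differentiable operation
returns a new :class:`Tensor` holding its forward value, references to its
parents and a closure that maps the output gradient to parent-gradient
contributions.  ``Tensor.backward`` walks the tape in reverse topological
order.  Only the operations the network needs are implemented; everything
is float32 and broadcasting follows NumPy semantics.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (evaluation mode) inside the block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros(self.data.shape, dtype=DTYPE)
        self.grad += g.astype(DTYPE, copy=False)

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor through the recorded tape."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        out = Tensor(self.data + other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = astensor(other)
        out = Tensor(self.data * other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __truediv__(self, other):
        other = astensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return astensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def bw(g):
                self._accumulate(_unbroadcast(g * p * self.data ** (p - 1.0), self.data.shape))
            out._backward = bw
        return out

    def __matmul__(self, other):
        other = astensor(other)
        out = Tensor(np.matmul(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                    self._accumulate(_unbroadcast(ga, self.data.shape))
                if other.requires_grad:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.data.shape))
            out._backward = bw
        return out

    # -- elementwise functions -------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (0.5 / val))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - val * val))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def silu(self):
        return self * self.sigmoid()

    def softplus(self):
        val = np.logaddexp(0.0, self.data)
        out = Tensor(val, requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-self.data))
            out._backward = lambda g: self._accumulate(g * sig)
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def bw(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape))
                    return
                gg = g
                if not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    for ax in sorted(a % self.data.ndim for a in axes):
                        gg = np.expand_dims(gg, ax)
                self._accumulate(np.broadcast_to(gg, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a % self.data.ndim]
             for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), requires_grad=self.requires_grad,
                     parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros(self.data.shape, dtype=DTYPE)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bw
        return out

    def roll(self, shift, axis):
        out = Tensor(np.roll(self.data, shift, axis=axis),
                     requires_grad=self.requires_grad, parents=(self,))
        if out.requires_grad:
            neg = tuple(-s for s in shift) if isinstance(shift, tuple) else -shift
            out._backward = lambda g: self._accumulate(np.roll(g, neg, axis=axis))
        return out


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=req, parents=tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    expanded = []
    for t in tensors:
        shape = list(t.data.shape)
        shape.insert(axis % (t.data.ndim + 1), 1)
        expanded.append(t.reshape(shape))
    return concat(expanded, axis=axis)


def take(x: Tensor, indices: np.ndarray, axis: int) -> Tensor:
    """Gather slices of ``x`` along ``axis`` (differentiable np.take)."""
    x = astensor(x)
    indices = np.asarray(indices)
    out = Tensor(np.take(x.data, indices, axis=axis),
                 requires_grad=x.requires_grad, parents=(x,))
    if out.requires_grad:
        def bw(g):
            full = np.zeros(x.data.shape, dtype=DTYPE)
            moved = np.moveaxis(full, axis, 0)
            gmoved = np.moveaxis(
                g, tuple(range(axis, axis + indices.ndim)),
                tuple(range(indices.ndim)))
            np.add.at(moved, indices, gmoved)
            x._accumulate(full)
        out._backward = bw
    return out
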