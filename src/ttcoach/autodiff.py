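"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine covering exactly the operations the variational
state-space model needs: arithmetic with broadcasting, matrix products,
tanh / sigmoid / exp / log / softplus, reductions and concatenation.
Gradients are accumulated by a topological backward sweep from a scalar
loss. The op set is deliberately closed and every op is gradient-checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "softplus", "sigmoid"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping an ``ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_a, bwd_b) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(fwd(self.data, other.data))
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._parents = (self, other)

            def _backward(g):
                if self.requires_grad or self._parents:
                    self._accum(_unbroadcast(bwd_a(g), self.data.shape))
                if other.requires_grad or other._parents:
                    other._accum(_unbroadcast(bwd_b(g), other.data.shape))

            out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g: g, lambda g: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g: g, lambda g: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        return self._binary(
            other, np.multiply, lambda g: g * other.data, lambda g: g * self.data
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self._binary(
            other,
            np.divide,
            lambda g: g / other.data,
            lambda g: -g * self.data / other.data**2,
        )

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data)
        out.requires_grad = self.requires_grad or other.requires_grad
        if out.requires_grad:
            out._parents = (self, other)

            def _backward(g):
                if self.requires_grad or self._parents:
                    self._accum(_unbroadcast(g @ other.data.T, self.data.shape))
                if other.requires_grad or other._parents:
                    other._accum(_unbroadcast(self.data.T @ g, other.data.shape))

            out._backward = _backward
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def _unary(self, fwd_val: np.ndarray, dlocal: np.ndarray) -> "Tensor":
        out = Tensor(fwd_val)
        out.requires_grad = self.requires_grad
        if out.requires_grad or self._parents:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g: self._accum(g * dlocal)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        return self._unary(y, 1.0 - y**2)

    def sigmoid(self):
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return self._unary(y, y * (1.0 - y))

    def exp(self):
        y = np.exp(self.data)
        return self._unary(y, y)

    def log(self):
        return self._unary(np.log(self.data), 1.0 / self.data)

    def softplus(self):
        # numerically stable log(1 + e^x)
        y = np.logaddexp(0.0, self.data)
        s = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return self._unary(y, s)

    def square(self):
        return self._unary(self.data**2, 2.0 * self.data)

    def sqrt(self):
        y = np.sqrt(self.data)
        return self._unary(y, 0.5 / y)

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out.requires_grad = self.requires_grad
        if out.requires_grad or self._parents:
            out.requires_grad = True
            out._parents = (self,)

            def _backward(g):
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

            out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape))
        out.requires_grad = self.requires_grad
        if out.requires_grad or self._parents:
            out.requires_grad = True
            out._parents = (self,)
            out._backward = lambda g: self._accum(g.reshape(orig))
        return out

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def sigmoid(x: Tensor) -> Tensor:
    return x.sigmoid()


def softplus(x: Tensor) -> Tensor:
    return x.softplus()


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis`` with gradient routing back to each input."""
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def _backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accum(piece)

        out._backward = _backward
    return out
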