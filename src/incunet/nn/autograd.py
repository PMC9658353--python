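"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` replays them in reverse topological order to
accumulate gradients.  Only the primitives needed by the network layers are
implemented (elementwise arithmetic with broadcasting, matmul, reductions,
relu/sigmoid/log, reshape/transpose, concatenation, clipping).  Convolution,
pooling and batch-norm register custom gradients via :func:`from_op`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "from_op", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "is_weight")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        # set True on parameters that Eq-style gaussian init should touch
        self.is_weight = False

    # -- construction helpers -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"

    # -- autodiff machinery ---------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth is unbounded in deep nets
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = from_op(self.data + other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = from_op(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = from_op(self.data * other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = from_op(self.data / other.data, (self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out = from_op(self.data**exponent, (self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1)
        )
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = from_op(self.data @ other.data, (self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = bwd
        return out

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = from_op(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = from_op(self.data.transpose(axes), (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    # -- nonlinearities -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = from_op(np.where(mask, self.data, 0.0), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = from_op(s, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def log(self):
        out = from_op(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclipped entries."""
        mask = (self.data > lo) & (self.data < hi)
        out = from_op(np.clip(self.data, lo, hi), (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out


def from_op(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    """Result tensor of a primitive; caller attaches ``_backward``."""
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad or p._parents for p in out._parents)
    return out


def concatenate(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = from_op(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bwd
    return out
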