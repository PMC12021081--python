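"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the model are implemented: dense linear
algebra, pointwise nonlinearities, reductions, row/column gathers for
embedding lookups and label indexing, and a gradient-reversal op whose
forward pass is the identity and whose backward pass multiplies the
incoming sensitivity by ``-scale``.

All tensors are float64; the engine favours exactness (finite-difference
checkable gradients) over speed, which is adequate at the data scales
this package targets.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "reverse_gradient"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple["Tensor", ...] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure ------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order of the graph rooted here
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g / other.data)
            if other.requires_grad:
                other._accumulate(-g * self.data / (other.data ** 2))

        out._backward = _bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data ** exponent, _parents=(self,))

        def _bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    # -- pointwise -----------------------------------------------------

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """max(x, lo); gradient is blocked where the clip is active."""
        mask = self.data > lo
        out = Tensor(np.maximum(self.data, lo), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    # -- reductions / reshaping ---------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def _bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    # -- gathers -------------------------------------------------------

    def take_rows(self, index: np.ndarray) -> "Tensor":
        """Row gather (embedding lookup); backward scatter-adds."""
        index = np.asarray(index)
        out = Tensor(self.data[index], _parents=(self,))

        def _bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, index, g)
            self._accumulate(acc)

        out._backward = _bw
        return out

    def gather(self, row_index: np.ndarray, col_index: np.ndarray) -> "Tensor":
        """Per-row element pick, e.g. predicted probability of the true label."""
        row_index = np.asarray(row_index)
        col_index = np.asarray(col_index)
        out = Tensor(self.data[row_index, col_index], _parents=(self,))

        def _bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, (row_index, col_index), g)
            self._accumulate(acc)

        out._backward = _bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def reverse_gradient(x: Tensor, scale: float = 1.0) -> Tensor:
    """Identity in the forward pass; multiplies the upstream sensitivity
    by ``-scale`` in the backward pass."""
    if scale <= 0:
        raise ValueError("reversal scale must be positive")
    out = Tensor(x.data, _parents=(x,))
    out._backward = lambda g: x._accumulate(-scale * g)
    return out
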