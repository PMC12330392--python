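"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains a small convolutional MIL network on CPU; this module
provides the tape it runs on.  A :class:`Tensor` wraps an ``ndarray`` and
records, for every derived tensor, its parent tensors and a closure that maps
the upstream gradient to per-parent gradients.  ``Tensor.backward`` performs a
topological sweep and accumulates gradients on every tensor that requires
them, including intermediates — which is what Grad-CAM reads.

Only the operations the network needs are implemented (elementwise
arithmetic with broadcasting, matmul, tanh/relu/sigmoid/exp/log, axis
reductions, reshape/transpose).  Convolution and spatial max-pooling live in
:mod:`sonomil.nn` as custom ops built on the same primitive.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "make_op"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # collapse axes that were broadcast from 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 1000  # keep ndarray.__mul__ from intercepting

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray]] | None = None

    # -- construction of derived tensors ------------------------------------

    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- basic properties ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        data = self.data + other.data
        return Tensor._op(
            data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        data = self.data * other.data
        return Tensor._op(
            data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        data = self.data / other.data
        return Tensor._op(
            data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        data = self.data**exponent
        return Tensor._op(
            data, (self,), lambda g: (g * exponent * self.data ** (exponent - 1),)
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:  # inner product
                return g * b, g * a
            if a.ndim == 1:  # (k,) @ (k, n) -> (n,)
                return g @ b.T, np.outer(a, g)
            if b.ndim == 1:  # (m, k) @ (k,) -> (m,)
                return np.outer(g, b), a.T @ g
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

        return Tensor._op(data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        data = np.exp(self.data)
        return Tensor._op(data, (self,), lambda g: (g * data,))

    def log(self):
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        data = np.tanh(self.data)
        return Tensor._op(data, (self,), lambda g: (g * (1.0 - data**2),))

    def relu(self):
        mask = self.data > 0
        return Tensor._op(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        # numerically stable logistic
        data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )
        return Tensor._op(data, (self,), lambda g: (g * data * (1.0 - data),))

    # -- reductions and shape ops ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._op(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / float(count)

    def max(self, axis=None, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            expanded = self.data.max(axis=axis, keepdims=True)
            mask = self.data == expanded
            mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly
            g = np.asarray(g)
            if not keepdims and axis is not None:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.ndim for a in axes):
                    g = np.expand_dims(g, ax)
            elif not keepdims and axis is None:
                g = np.broadcast_to(g, (1,) * self.ndim)
            return (mask * g,)

        return Tensor._op(data, (self,), backward)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = tuple(np.argsort(axes))
        return Tensor._op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inverse),)
        )

    @property
    def T(self):
        return self.transpose(*reversed(range(self.ndim)))

    # -- backward pass ---------------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every tensor in its graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; bags can produce deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in seen and parent.requires_grad:
                    stack.append((parent, False))

        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.shape)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                g = np.asarray(g).reshape(parent.shape)
                parent.grad = g if parent.grad is None else parent.grad + g


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def make_op(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    """Public hook for custom ops (used by conv/pool layers)."""
    return Tensor._op(data, tuple(as_tensor(p) for p in parents), backward)
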