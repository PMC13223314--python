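"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` together with an optional gradient and
the closure needed to propagate adjoints to its inputs.  The op set is exactly
what the models in this package need: broadcast-aware arithmetic, matmul /
tensordot contractions, reductions, the usual pointwise nonlinearities, a
softmax with a dedicated Jacobian-vector product, and strided 1-D
convolution / transposed convolution (see :mod:`semglearn.nn.layers`).

Gradients are accumulated by a topological-order backward sweep from the
scalar loss.  Correctness of every op is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # Leading axes added by broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # Axes of size 1 that were stretched.
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Iterable["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this scalar through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._wrap(other))

    def __rsub__(self, other) -> "Tensor":
        return self._wrap(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __pow__(self, p: float) -> "Tensor":
        return self.pow(p)

    def matmul(self, other) -> "Tensor":
        """2-D weight contraction: supports (..., D) @ (D, M)."""
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            axes = tuple(range(self.data.ndim - 1))
            other._accumulate(np.tensordot(self.data, g, axes=(axes, axes)))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise ---------------------------------------------------------

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def leaky_relu(self, alpha: float) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, alpha)
        )
        return out

    def clip_min(self, lo: float) -> "Tensor":
        """Lower clamp; gradient flows only where the input was above ``lo``."""
        out = Tensor(np.maximum(self.data, lo), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > lo))
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        out._backward = bwd
        return out

    def concat(self, others: list["Tensor"], axis: int) -> "Tensor":
        parts = [self] + list(others)
        out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _prev=parts)
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                p._accumulate(g[tuple(sl)])

        out._backward = bwd
        return out

    # -- softmax -----------------------------------------------------------

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, _prev=(self,))

        def bwd(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accumulate(p * (g - dot))

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable leaf; ``trainable=False`` freezes it for every optimizer."""

    __slots__ = ("trainable",)

    def __init__(self, data, trainable: bool = True):
        super().__init__(data, requires_grad=True)
        self.trainable = trainable
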