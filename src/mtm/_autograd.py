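"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small dense stacks, so a compact tape-based
engine is sufficient: a :class:`Tensor` wraps a float64 ndarray, records the
operations applied to it, and :meth:`Tensor.backward` runs the reverse sweep
in topological order.  All arithmetic is double precision and single-threaded
numpy, which makes seeded runs bit-reproducible.

Supported operations are exactly the ones the model needs: affine maps,
broadcasting add/mul, leaky ReLU, absolute value, clamped hinge terms, row
gathering (for per-tissue affine parameters) and mean/sum reductions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes that were added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- helpers -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        """Return a view of the data cut off from the tape."""
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(g)
            if other.requires_grad or other._prev:
                other._accumulate(g)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(g * other.data)
            if other.requires_grad or other._prev:
                other._accumulate(g * self.data)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def backward(g):
            if self.requires_grad or self._prev:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accumulate(self.data.T @ g)

        out._backward = backward
        return out

    def __matmul__(self, other):
        return self.matmul(other)

    # -- nonlinearities ----------------------------------------------------

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data),
                     self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(mask, 1.0, slope))
        return out

    def relu(self) -> "Tensor":
        return self.leaky_relu(0.0)

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * sign)
        return out

    # -- indexing / reductions --------------------------------------------

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Select rows by integer index (embedding-style lookup)."""
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = backward
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(np.asarray(g) / n, self.data.shape))
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(np.asarray(g), self.data.shape))
        return out

    # -- autodiff ----------------------------------------------------------

    def backward(self) -> None:
        """Reverse sweep from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; cycle-free by construction
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

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list, lr: float = 5e-4,
                 beta1: float = 0.5, beta2: float = 0.9, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
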