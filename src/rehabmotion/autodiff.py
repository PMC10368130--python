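"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine — just the operations the assessment network
needs: broadcast arithmetic, matmul, sigmoid/tanh/relu, concatenation,
slicing, reshaping, reductions.  Gradients accumulate on leaf tensors
marked ``requires_grad``; ``Tensor.backward()`` runs the reverse sweep
in topological order.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting introduced."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers --------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, self.shape))
            other._accumulate(_unbroadcast(gb, other.shape))
        out._backward = bw
        return out

    # -- nonlinearities --------------------------------------------------
    def sigmoid(self):
        # overflow of exp(-x) saturates cleanly to 0; silence the warning
        with np.errstate(over="ignore"):
            s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - t * t))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(old))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))
        basic = isinstance(key, (int, slice)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (int, slice)) for k in key))

        def bw(g):
            # write straight into the parent grad buffer: avoids a
            # full-size temporary per slice (hot path in the recurrences)
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            if basic:          # basic indexing never aliases: plain add
                self.grad[key] += g
            else:
                np.add.at(self.grad, key, g)
        out._backward = bw
        return out

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = (self.data.size if axis is None
             else np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- reverse sweep ---------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        order: List[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def bw(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))
    out._backward = bw
    return out


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
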