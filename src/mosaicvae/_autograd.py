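"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is a modular variational autoencoder whose loss
graph (product-of-experts posterior, reparameterized samples feeding several
coupled penalties, adversarial classifiers with selectively frozen parameter
groups) is assembled dynamically per minibatch.  This module provides the
small vectorized tape needed to train it: a :class:`Tensor` wrapping an
``ndarray`` plus the elementwise / linear-algebra primitives the networks
use.  Gradients are checked against central finite differences in the test
suite.

Only what the package needs is implemented: broadcasting binary ops, matmul,
the usual nonlinearities, reductions, indexing and concatenation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g)
                if other.requires_grad:
                    other._accum(g)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g * other.data)
                if other.requires_grad:
                    other._accum(g * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g / other.data)
                if other.requires_grad:
                    other._accum(-g * self.data / other.data ** 2)
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)
            out._backward = bw
        return out

    # ------------------------------------------------------------- elementwise
    def exp(self):
        v = np.exp(self.data)
        out = Tensor(v, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * v)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        v = np.sqrt(self.data)
        out = Tensor(v, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / v)
        return out

    def tanh(self):
        v = np.tanh(self.data)
        out = Tensor(v, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - v ** 2))
        return out

    def sigmoid(self):
        v = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(v, parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * v * (1.0 - v))
        return out

    def softplus(self):
        # numerically stable log(1+exp(x))
        v = np.logaddexp(0.0, self.data)
        out = Tensor(v, parents=(self,))
        if out.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
            out._backward = lambda g: self._accum(g * s)
        return out

    def mish(self):
        """x * tanh(softplus(x))."""
        return self * self.softplus().tanh()

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes through only inside [lo, hi]."""
        v = np.clip(self.data, lo, hi)
        out = Tensor(v, parents=(self,))
        if out.requires_grad:
            inside = (self.data >= lo) & (self.data <= hi)
            out._backward = lambda g: self._accum(g * inside)
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        if out.requires_grad:
            def bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.data.shape))
                else:
                    ge = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(ge, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def logsumexp(self, axis: int, keepdims: bool = False):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - Tensor(m)
        out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
        if not keepdims:
            out = out.reshape(tuple(d for i, d in enumerate(out.shape) if i != axis))
        return out

    # ------------------------------------------------------------ shape & index
    def reshape(self, shape):
        out = Tensor(self.data.reshape(shape), parents=(self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
            out._backward = bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out
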