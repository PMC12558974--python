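"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the forecaster needs: broadcasting
elementwise arithmetic, 2-D matrix products, sigmoid/tanh/ELU/exp,
reductions, reshape/slicing/concatenation and a numerically stable
softmax. Gradients flow through a dynamically recorded tape and are
accumulated by a topological backward sweep. Correctness is checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "elu", "softmax", "concatenate", "stack", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph machinery -------------------------------------------------
    def backward(self, grad=None) -> None:
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=float), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * other.data)
            if other.requires_grad:
                other._accumulate(g * self.data)
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ g)
        out._backward = bwd
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))
        out._backward = bwd
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
        out._backward = bwd
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- nonlinearities --------------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)
        out._backward = bwd
        return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))
    out._backward = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))
    out._backward = bwd
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    pos = x.data > 0
    val = np.where(pos, x.data, alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0))
    out = Tensor(val, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * np.where(pos, 1.0, val + alpha))
    out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # the detached max shift does not affect the derivative
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    out._backward = bwd
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _parents=tuple(tensors))

    def bwd(g):
        slabs = np.moveaxis(g, axis, 0)
        for t, slab in zip(tensors, slabs):
            if t.requires_grad:
                t._accumulate(slab)
    out._backward = bwd
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
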