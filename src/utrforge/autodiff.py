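"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical engine behind the convolutional MRL predictor, the
sequence VAE, the deep-exploration generator and the gradient-based
sequence optimizer.  It implements exactly the operator set those models
need (dense/convolutional algebra, ReLU, softmax pieces, pooling,
gather/pad for im2col) with a topological-sort backward pass.  Gradients
are float64 and are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "relu", "softmax", "logsumexp", "concat", "stack_last"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
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

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.shape))
        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))
        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                go = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(go, other.shape))
        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -----------------------------------------
    def relu(self):
        mask = self.data > 0
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1 - out_data))
        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1 - out_data**2))
        return self._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # ties: split gradient evenly (deterministic, matches subgradient)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        def backward(g):
            if self.requires_grad:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(gg * mask)
        return self._make(
            out_data if keepdims else out_data.squeeze(axis=axis), (self,), backward
        )

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))
        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(*inv))
        return self._make(self.data.transpose(*axes), (self,), backward)

    def take_axis1(self, indices: np.ndarray):
        """Gather along axis 1: (N, L, ...) -> (N, *indices.shape, ...)."""
        indices = np.asarray(indices)
        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                flat = g.reshape((g.shape[0], indices.size) + self.shape[2:])
                np.add.at(acc, (slice(None), indices.ravel()), flat)
                self._accumulate(acc)
        return self._make(self.data[:, indices], (self,), backward)

    def pad_axis1(self, before: int, after: int):
        widths = [(0, 0)] * self.data.ndim
        widths[1] = (before, after)
        L = self.shape[1]
        def backward(g):
            if self.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[1] = slice(before, before + L)
                self._accumulate(g[tuple(sl)])
        return self._make(np.pad(self.data, widths), (self,), backward)

    def __getitem__(self, key):
        fancy = any(
            isinstance(k, (np.ndarray, list)) for k in (key if isinstance(key, tuple) else (key,))
        )
        def backward(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                if fancy:
                    np.add.at(acc, key, g)
                else:
                    acc[key] += g
                self._accumulate(acc)
        return self._make(self.data[key], (self,), backward)


# ---------------------------------------------------------------------------
# functional helpers


def relu(x: Tensor) -> Tensor:
    return x.relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def logsumexp(x: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    out = (x - m).exp().sum(axis=axis, keepdims=True).log() + m
    if not keepdims:
        sq = out.reshape(*np.delete(np.array(out.shape), axis))
        return sq
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def backward(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accumulate(p)
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack_last(tensors: Sequence[Tensor]) -> Tensor:
    """Stack scalars/vectors along a new last axis."""
    return concat([t.reshape(*t.shape, 1) for t in tensors], axis=-1)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
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
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
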