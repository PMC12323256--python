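"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the integration model needs: broadcasted
arithmetic, matmul, reductions, the stable link functions (softplus, sigmoid,
log-sigmoid) and row gather/scatter for mosaic modality masks. Gradients are
accumulated by topological-order backpropagation from a scalar loss.

The engine is deliberately small; it is not a general tensor library. All
computation is float64 and single-threaded, which keeps training bitwise
deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient slot and a backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, grad={self.requires_grad})"

    @staticmethod
    def _make(value, parents, backward, requires_grad):
        out = Tensor(value, requires_grad=requires_grad)
        if requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return Tensor._make(self.value + other.value, (self, other), backward, rg)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.value, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.value)
            if other.requires_grad:
                other._accum(g * self.value)

        return Tensor._make(self.value * other.value, (self, other), backward, rg)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(g / other.value)
            if other.requires_grad:
                other._accum(-g * self.value / other.value**2)

        return Tensor._make(self.value / other.value, (self, other), backward, rg)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.value ** (p - 1))

        return Tensor._make(self.value**p, (self,), backward, self.requires_grad)

    def __matmul__(self, other):
        other = as_tensor(other)
        rg = self.requires_grad or other.requires_grad

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.value.T)
            if other.requires_grad:
                other._accum(self.value.T @ g)

        return Tensor._make(self.value @ other.value, (self, other), backward, rg)

    @property
    def T(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor._make(self.value.T, (self,), backward, self.requires_grad)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.value.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.value.shape))

        return Tensor._make(
            self.value.sum(axis=axis, keepdims=keepdims), (self,), backward, self.requires_grad
        )

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_val = np.exp(self.value)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_val)

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.value)

        return Tensor._make(np.log(self.value), (self,), backward, self.requires_grad)

    def sqrt(self):
        out_val = np.sqrt(self.value)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_val)

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def relu(self):
        mask = self.value > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.value * mask, (self,), backward, self.requires_grad)

    def softplus(self):
        # stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        out_val = np.maximum(self.value, 0.0) + np.log1p(np.exp(-np.abs(self.value)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.value, -700, 700)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def sigmoid(self):
        out_val = 1.0 / (1.0 + np.exp(-np.clip(self.value, -700, 700)))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_val * (1.0 - out_val))

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def logsigmoid(self):
        # stable: log sigmoid(x) = min(x,0) - log1p(exp(-|x|))
        out_val = np.minimum(self.value, 0.0) - np.log1p(np.exp(-np.abs(self.value)))
        sig = 1.0 / (1.0 + np.exp(np.clip(self.value, -700, 700)))  # = 1 - sigmoid(x)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sig)

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo (hinge convention)."""
        mask = self.value > lo

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(np.maximum(self.value, lo), (self,), backward, self.requires_grad)

    # ------------------------------------------------------------- row indexing
    def gather_rows(self, index: np.ndarray):
        index = np.asarray(index, dtype=np.intp)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, index, g)
                self._accum(full)

        return Tensor._make(self.value[index], (self,), backward, self.requires_grad)

    def scatter_rows(self, index: np.ndarray, n_rows: int):
        """Place row i of self at position index[i] in an (n_rows, d) zero matrix."""
        index = np.asarray(index, dtype=np.intp)
        out_val = np.zeros((n_rows,) + self.value.shape[1:], dtype=np.float64)
        np.add.at(out_val, index, self.value)

        def backward(g):
            if self.requires_grad:
                self._accum(g[index])

        return Tensor._make(out_val, (self,), backward, self.requires_grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
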