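"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains small convolutional models and the attentive pairwise
interaction block with plain NumPy; this module supplies the scalar-loss
backpropagation machinery those components need (broadcast-aware
elementwise ops, matmul, softmax, and a handful of nonlinearities).
Gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat"]

_LOG_CLAMP = 1e-12  # floor inside log(); keeps degenerate probabilities finite


def _as_array(x, dtype=None):
    a = np.asarray(x, dtype=dtype)
    if a.dtype.kind not in "fc":
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
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
    """An n-d array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "trainable")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        self.data = _as_array(data, dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self.trainable = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p._needs_grad for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def _needs_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep for many-epoch loops)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p._parents:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self._needs_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other._needs_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self._needs_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self._needs_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other._needs_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self._needs_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other._needs_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bwd(g):
            if self._needs_grad:
                self._accum(g @ other.data.T)
            if other._needs_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self._needs_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            if self._needs_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self._needs_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def bwd(g):
            if self._needs_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self._needs_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        """Natural log with a 1e-12 floor; gradient is zero on the floor."""
        clamped = np.maximum(self.data, _LOG_CLAMP)
        mask = self.data > _LOG_CLAMP

        def bwd(g):
            if self._needs_grad:
                self._accum(g * mask / clamped)

        return Tensor._make(np.log(clamped), (self,), bwd)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            if self._needs_grad:
                inner = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - inner))

        return Tensor._make(p, (self,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo) elementwise; hinge losses use lo=0."""
        mask = self.data > lo

        def bwd(g):
            if self._needs_grad:
                self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, lo), (self,), bwd)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t._needs_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )
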