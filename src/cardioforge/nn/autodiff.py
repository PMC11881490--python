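"""Reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core the package's neural models are built on: a
:class:`Tensor` wrapping an ``ndarray`` plus the handful of differentiable
primitives needed for transformer blocks (matmul, softmax, layer
statistics), graph attention (gather / segment-sum over edge lists) and the
usual pointwise nonlinearities.  Gradients are accumulated by a topological
backward sweep; broadcasting is handled by summing gradients back over the
broadcast axes.

Everything runs in float64 on CPU.  The engine is deliberately minimal —
no graph pruning, no in-place ops — because model sizes in this package
are desk scale.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "Tensor",
    "concat",
    "embedding_lookup",
    "gather_rows",
    "segment_sum",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = None
        self.name = name

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" '{self.name}'" if self.name else ""
        return f"Tensor{tag}(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- autograd plumbing ---------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if self.requires_grad or self._parents:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if g.ndim else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accumulate(_unbroadcast(ga, a.shape))
            if other.requires_grad or other._parents:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)

        out._backward = bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities --------------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        out = Tensor(np.sqrt(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * 0.5 / out.data)
        return out

    def abs(self) -> "Tensor":
        out = Tensor(np.abs(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.sign(self.data))
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data**2))
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0.0))
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0.0, self.data, slope * self.data), _parents=(self,))
        out._backward = lambda g: self._accumulate(g * np.where(self.data > 0.0, 1.0, slope))
        return out

    def gelu(self) -> "Tensor":
        """Exact Gaussian-error-linear-unit: x * Phi(x)."""
        x = self.data
        phi = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out = Tensor(x * phi, _parents=(self,))
        pdf = np.exp(-0.5 * x**2) / math.sqrt(2.0 * math.pi)
        out._backward = lambda g: self._accumulate(g * (phi + x * pdf))
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def softplus(self) -> "Tensor":
        """log(1 + e^x), computed stably; gradient is the sigmoid."""
        x = self.data
        out = Tensor(np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))), _parents=(self,))
        out._backward = lambda g: self._accumulate(g / (1.0 + np.exp(-x)))
        return out

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _parents=(self,))

        def bw(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self._accumulate(y * (g - dot))

        out._backward = bw
        return out

    def log_softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        y = z - lse
        out = Tensor(y, _parents=(self,))

        def bw(g):
            self._accumulate(g - np.exp(y) * g.sum(axis=axis, keepdims=True))

        out._backward = bw
        return out


# -- free functions ----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out._backward = bw
    return out


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(table.data[ids], _parents=(table,))

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(full)

    out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """``x[index]`` along axis 0 (used to pull node states onto edges)."""
    index = np.asarray(index, dtype=np.int64)
    out = Tensor(x.data[index], _parents=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        np.add.at(full, index, g)
        x._accumulate(full)

    out._backward = bw
    return out


def segment_sum(x: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets (edge→node aggregation)."""
    segment_ids = np.asarray(segment_ids, dtype=np.int64)
    shape = (num_segments,) + x.data.shape[1:]
    acc = np.zeros(shape, dtype=np.float64)
    np.add.at(acc, segment_ids, x.data)
    out = Tensor(acc, _parents=(x,))
    out._backward = lambda g: x._accumulate(g[segment_ids])
    return out
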