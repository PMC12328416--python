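"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  The op set is exactly what a pre-norm
vision transformer needs: broadcasting arithmetic, (batched) matmul, row
gather/concat for token masking, reductions, and the nonlinearities GELU,
sigmoid, softmax.  Everything runs in float64 for headroom in gradient
checks; model code is free to pass float32 data.

The engine is deliberately eager and graph-per-call: desk-scale models here
have a few hundred thousand parameters and sequences of at most a few
hundred tokens, where numpy throughput dominates Python overhead.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concat", "gelu", "sigmoid", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = (), name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents = _parents
        self.name = name

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = Tensor._wrap(other)
        out = Tensor(fwd(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def _backward() -> None:
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, np.add, lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, np.subtract, lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._wrap(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, np.multiply, lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, np.divide,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor._wrap(other).__truediv__(self)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, exponent: float):
        assert np.isscalar(exponent)
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def _backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _parents=(self, other))

        def _backward() -> None:
            g = out.grad
            a, b = self.data, other.data
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.outer(g, b) if a.ndim == 2 else g[..., None] * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.outer(a, g) if b.ndim == 2 else a[..., None] * g
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = _backward
        return out

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def _backward() -> None:
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))

        def _backward() -> None:
            if self.requires_grad:
                self._accum(np.swapaxes(out.grad, a, b))

        out._backward = _backward
        return out

    @property
    def T(self) -> "Tensor":
        return self.swapaxes(-1, -2)

    def gather_rows(self, index) -> "Tensor":
        """Select rows (axis -2 for 2-D input: axis 0) by integer index."""
        index = np.asarray(index, dtype=np.intp)
        out = Tensor(self.data[index], self.requires_grad, (self,))

        def _backward() -> None:
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, index, out.grad)
                self._accum(g)

        out._backward = _backward
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def _backward() -> None:
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def _backward() -> None:
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        return self ** 0.5


def sigmoid(x: Tensor) -> Tensor:
    y = _sp.expit(x.data)
    out = Tensor(y, x.requires_grad, (x,))

    def _backward() -> None:
        if x.requires_grad:
            x._accum(out.grad * out.data * (1.0 - out.data))

    out._backward = _backward
    return out


def gelu(x: Tensor) -> Tensor:
    """Exact (erf) Gaussian error linear unit."""
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    cdf = 0.5 * (1.0 + _sp.erf(x.data * inv_sqrt2))
    out = Tensor(x.data * cdf, x.requires_grad, (x,))

    def _backward() -> None:
        if x.requires_grad:
            pdf = np.exp(-0.5 * x.data * x.data) / math.sqrt(2.0 * math.pi)
            x._accum(out.grad * (cdf + x.data * pdf))

    out._backward = _backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis`; rows sum to one."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def _backward() -> None:
        if x.requires_grad:
            g = out.grad
            dot = (g * out.data).sum(axis=axis, keepdims=True)
            x._accum(out.data * (g - dot))

    out._backward = _backward
    return out


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = list(tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward() -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = _backward
    return out
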