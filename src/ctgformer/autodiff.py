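"""Minimal reverse-mode automatic differentiation over numpy arrays.

The transformer in :mod:`ctgformer.model` needs gradients of a scalar loss
with respect to a few dozen weight matrices.  This module provides exactly
the primitives that network uses — broadcast-aware elementwise arithmetic,
batched matrix multiplication, reductions, a handful of activations and a
gather — each with an analytic backward rule.  Gradients are accumulated by
a topological sweep over the recorded computation graph.

All data is float64; correctness over speed.  Gradient correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf, expit as _expit

__all__ = ["Tensor", "concatenate"]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure that back-propagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._prev = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bwd(g):
            a._accum(g)
            b._accum(g)

        return self._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return self._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bwd(g):
            a._accum(g * b.data)
            b._accum(g * a.data)

        return self._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, p: float):
        a = self

        def bwd(g):
            a._accum(g * p * a.data ** (p - 1.0))

        return self._make(a.data**p, (a,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def bwd(g):
            a._accum(g @ np.swapaxes(b.data, -1, -2))
            b._accum(np.swapaxes(a.data, -1, -2) @ g)

        return self._make(a.data @ b.data, (a, b), bwd)

    # ------------------------------------------------------------ activations
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return self._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return self._make(out_data, (a,), lambda g: a._accum(g * (1.0 - out_data**2)))

    def relu(self):
        a = self
        return self._make(
            np.maximum(a.data, 0.0), (a,), lambda g: a._accum(g * (a.data > 0))
        )

    def elu(self, alpha: float = 1.0):
        a = self
        pos = a.data > 0
        out_data = np.where(pos, a.data, alpha * np.expm1(a.data))
        return self._make(
            out_data, (a,), lambda g: a._accum(g * np.where(pos, 1.0, out_data + alpha))
        )

    def gelu(self):
        # exact form: x * Phi(x) with Phi the standard normal CDF
        a = self
        phi_cdf = 0.5 * (1.0 + _erf(a.data / _SQRT2))
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data**2)
        return self._make(
            a.data * phi_cdf, (a,), lambda g: a._accum(g * (phi_cdf + a.data * pdf))
        )

    def sigmoid(self):
        a = self
        s = _expit(a.data)
        return self._make(s, (a,), lambda g: a._accum(g * s * (1.0 - s)))

    def softplus(self):
        # log(1 + e^x), numerically stable; gradient is the sigmoid
        a = self
        return self._make(
            np.logaddexp(0.0, a.data), (a,), lambda g: a._accum(g * _expit(a.data))
        )

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ shape moves
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return self._make(
            a.data.reshape(shape), (a,), lambda g: a._accum(g.reshape(a.data.shape))
        )

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)
        return self._make(
            a.data.transpose(axes), (a,), lambda g: a._accum(g.transpose(inv))
        )

    def swapaxes(self, ax1: int, ax2: int):
        a = self
        return self._make(
            np.swapaxes(a.data, ax1, ax2), (a,), lambda g: a._accum(np.swapaxes(g, ax1, ax2))
        )

    def gather_last(self, index: np.ndarray):
        """Fancy-index the last axis: out[..., i, j] = x[..., index[i, j]].

        Used to cut a length-L series into patches; the backward pass
        scatter-adds because overlapping patches reuse samples.
        """
        a = self
        index = np.asarray(index)

        def bwd(g):
            buf = np.zeros_like(a.data)
            np.add.at(buf, (Ellipsis, index), g)
            a._accum(buf)

        return self._make(a.data[..., index], (a,), bwd)

    # ------------------------------------------------------- composite helpers
    def softmax(self, axis: int = -1):
        shift = self - np.max(self.data, axis=axis, keepdims=True)  # constant shift
        e = shift.exp()
        return e / e.sum(axis=axis, keepdims=True)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd
    )
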