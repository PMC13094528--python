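"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a small encoder-decoder transformer: broadcast
-aware elementwise ops, batched matmul, reductions, embedding gather and
a log-softmax gather for the cross-entropy.  Gradients accumulate in
``Tensor.grad`` after :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=rg, parents=parents if rg else (),
                      backward=backward if rg else None)

    # -- elementwise ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._node(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        return self._node(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._node(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self**-1.0

    def __pow__(self, p: float):
        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._node(self.data**p, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._node(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._node(self.data * mask, (self,), bwd)

    # -- shape ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._node(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        return self._node(self.data.transpose(*axes), (self,), bwd)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, 1.0) * g)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- linear algebra ---------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._lift(other)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return self._node(np.matmul(self.data, other.data), (self, other), bwd)

    __matmul__ = matmul

    # -- indexing ---------------------------------------------------------
    def take_rows(self, idx: np.ndarray):
        """Embedding lookup: rows of a 2-D tensor by an integer array."""
        idx = np.asarray(idx)

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
                self._accum(acc)

        return self._node(self.data[idx], (self,), bwd)

    def gather_last(self, idx: np.ndarray):
        """Pick one entry per position along the last axis."""
        idx = np.asarray(idx)
        picked = np.take_along_axis(self.data, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.put_along_axis(acc, idx[..., None], g[..., None], axis=-1)
                self._accum(acc)

        return self._node(picked, (self,), bwd)

    # -- compound ---------------------------------------------------------
    def softmax(self):
        """Softmax over the last axis (shift-invariant, stable)."""
        shifted = self - self.data.max(axis=-1, keepdims=True)
        e = shifted.exp()
        return e / e.sum(axis=-1, keepdims=True)

    def log_softmax(self):
        m = self.data.max(axis=-1, keepdims=True)
        shifted = self - m
        lse = shifted.exp().sum(axis=-1, keepdims=True).log()
        return shifted - lse

    # -- autodiff ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)
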