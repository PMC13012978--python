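"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the segmentation network
needs: broadcast arithmetic, batched matrix products, pointwise
nonlinearities, reductions, reshaping and concatenation.  Convolution,
pooling, normalization and interpolation live in :mod:`sectnet.nn` and
build on the same :class:`Tensor` graph.

Gradients are accumulated by a closure attached to each output tensor;
``Tensor.backward()`` runs the closures in reverse topological order.
All data is float32.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "concat"]


def _f32(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float32)
    return arr


def unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = unbroadcast(_f32(g), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # ---- basic properties ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(()))

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- autograd driver --------------------------------------------------
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
        self._accum(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        other = as_tensor(other)
        out_data = self.data - other.data

        def bw(g):
            self._accum(g)
            other._accum(-g)

        return Tensor._make(out_data, (self, other), bw)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / (other.data * other.data))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bw)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            self._accum(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accum(np.matmul(np.swapaxes(self.data, -1, -2), g))

        return Tensor._make(out_data, (self, other), bw)

    __matmul__ = matmul

    # ---- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, 0.0).astype(np.float32)

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def leaky_relu(self, alpha: float = 0.01) -> "Tensor":
        mask = self.data > 0
        out_data = np.where(mask, self.data, alpha * self.data).astype(np.float32)

        def bw(g):
            self._accum(g * np.where(mask, 1.0, alpha).astype(np.float32))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self) -> "Tensor":
        # numerically stable logistic
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def bw(g):
            self._accum(g * inside)

        return Tensor._make(out_data, (self,), bw)

    # ---- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis, keepdims: bool = False) -> "Tensor":
        """Max over axes; ties share the gradient equally."""
        out_keep = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_keep
        count = mask.sum(axis=axis, keepdims=True)
        out_data = out_keep if keepdims else np.squeeze(out_keep, axis=axis)

        def bw(g):
            gg = np.asarray(g)
            if not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accum(mask * (gg / count))

        return Tensor._make(out_data, (self,), bw)

    # ---- shape manipulation ------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accum(np.asarray(g).reshape(self.data.shape))

        return Tensor._make(out_data, (self,), bw)


class Parameter(Tensor):
    """A tensor that is always a leaf with ``requires_grad=True``."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis`` (differentiable)."""
    ts = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._make(out_data, ts, bw)
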