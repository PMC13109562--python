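"""Minimal reverse-mode tensor autodiff core.

Float64 tensors over numpy with exactly the primitives the detector needs:
broadcasting arithmetic, matmul, sigmoid/relu/exp/log/abs, elementwise
max/min, reductions, reshape/transpose/concat, small-kernel 2-D convolution
(im2col), and nearest-neighbour resampling. Gradients are accumulated by a
topological backward pass; correctness is pinned by finite-difference checks
in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "sigmoid", "relu", "exp", "log", "absolute",
           "maximum", "minimum", "conv2d", "resample_nearest", "softmax_lastdim"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
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
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        parents = tuple(p for p in parents if isinstance(p, Tensor))
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
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
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out = self._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1.0))

        out = self._make(out_data, (self,), backward)
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward():
            g = out.grad
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out = self._make(out_data, (self, other), backward)
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out = self._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out = self._make(out_data, (self,), backward)
        return out

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        out_data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))

        out = self._make(out_data, (self,), backward)
        return out

    @property
    def T(self):
        return self.transpose()


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * out_data)

    out = Tensor._make(out_data, (x,), backward)
    return out


def log(x: Tensor) -> Tensor:
    out_data = np.log(x.data)

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad / x.data)

    out = Tensor._make(out_data, (x,), backward)
    return out


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * out_data * (1.0 - out_data))

    out = Tensor._make(out_data, (x,), backward)
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * mask)

    out = Tensor._make(x.data * mask, (x,), backward)
    return out


def absolute(x: Tensor) -> Tensor:
    sign = np.sign(x.data)

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * sign)

    out = Tensor._make(np.abs(x.data), (x,), backward)
    return out


def maximum(a: Tensor, b) -> Tensor:
    b = Tensor._wrap(b)
    out_data = np.maximum(a.data, b.data)
    take_a = a.data >= b.data  # subgradient: ties route to the first argument

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    out = Tensor._make(out_data, (a, b), backward)
    return out


def minimum(a: Tensor, b) -> Tensor:
    b = Tensor._wrap(b)
    out_data = np.minimum(a.data, b.data)
    take_a = a.data <= b.data

    def backward():
        g = out.grad
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * ~take_a, b.data.shape))

    out = Tensor._make(out_data, (a, b), backward)
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward():
        g = out.grad
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), backward)
    return out


def softmax_lastdim(x: Tensor) -> Tensor:
    """Softmax over the last axis (shift by a detached max for stability)."""
    shift = x - Tensor(x.data.max(axis=-1, keepdims=True))
    e = exp(shift)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int,
            h_out: int, w_out: int) -> np.ndarray:
    c = xp.shape[0]
    cols = np.empty((c, kh, kw, h_out, w_out), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, i, j] = xp[:, i:i + stride * h_out:stride, j:j + stride * w_out:stride]
    return cols.reshape(c * kh * kw, h_out * w_out)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution of a (C_in, H, W) map with (C_out, C_in, kh, kw) weights."""
    c_in, h, w = x.data.shape
    c_out, c_in_w, kh, kw = weight.data.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, weight {c_in_w}")
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding)))
    h_out = (h + 2 * padding - kh) // stride + 1
    w_out = (w + 2 * padding - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, h_out, w_out)
    w2 = weight.data.reshape(c_out, -1)
    out_data = (w2 @ cols).reshape(c_out, h_out, w_out)
    if bias is not None:
        out_data = out_data + bias.data[:, None, None]

    def backward():
        g = out.grad.reshape(c_out, -1)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=1))
        if weight.requires_grad:
            weight._accumulate((g @ cols.T).reshape(weight.data.shape))
        if x.requires_grad:
            dcols = (w2.T @ g).reshape(c_in, kh, kw, h_out, w_out)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + stride * h_out:stride, j:j + stride * w_out:stride] += dcols[:, i, j]
            if padding:
                dxp = dxp[:, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(out_data, parents, backward)
    return out


def resample_nearest(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Nearest-neighbour resampling of a (C, H, W) map to exactly (C, out_h, out_w)."""
    c, h, w = x.data.shape
    rows = np.floor(np.arange(out_h) * h / out_h).astype(int)
    cols = np.floor(np.arange(out_w) * w / out_w).astype(int)
    out_data = x.data[:, rows[:, None], cols[None, :]]

    def backward():
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), rows[:, None], cols[None, :]), out.grad)
        x._accumulate(dx)

    out = Tensor._make(out_data, (x,), backward)
    return out
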