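"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float32 ``ndarray`` together with an optional
gradient and a closure that propagates incoming gradients to its parents.
``backward()`` runs a topological sweep over the recorded tape.  The op set
is deliberately small: exactly what a convolutional instance-segmentation
network needs (dense/grouped convolution, matmul, elementwise arithmetic,
reductions, sigmoid/ReLU/hard-swish, spatial resampling via interpolation
matrices, padding, concatenation and fancy gather).

Gradient tracking can be suspended globally with :func:`no_grad` — used for
inference so the forward pass allocates no tape.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph construction."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A differentiable array node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make ndarray <op> Tensor defer to the Tensor reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, dtype=np.float32):
        self.data = np.asarray(data, dtype=dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, dtype=np.asarray(data).dtype)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free tape memory eagerly; leaf grads persist
                node._backward = None
                node._parents = ()

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._make(out_data, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        return Tensor._make(out_data, (self, other), bw)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(out_data, (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]
        orig_shape = self.shape

        def bw(g):
            full = np.zeros(orig_shape, dtype=np.float32)
            np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape).astype(np.float32))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise nonlinearities --------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        out_data = np.log(self.data)

        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(out_data, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        # numerically stable logistic
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ez = np.exp(self.data[~pos])
        out_data[~pos] = ez / (1.0 + ez)

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bw)

    def hardswish(self):
        """x * relu6(x + 3) / 6 — the mobile-network hard-swish."""
        x = self.data
        inner = np.clip(x + 3.0, 0.0, 6.0)
        out_data = x * inner / 6.0

        def bw(g):
            d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
            self._accumulate(g * d.astype(np.float32))

        return Tensor._make(out_data, (self,), bw)

    def clip_min(self, lo: float):
        mask = self.data > lo
        out_data = np.maximum(self.data, lo)

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, bw)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tensors, bw)


def take_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Gather rows ``x[index]`` along axis 0 (integer index array)."""
    index = np.asarray(index, dtype=np.int64)
    out_data = x.data[index]
    shape = x.shape

    def bw(g):
        full = np.zeros(shape, dtype=np.float32)
        np.add.at(full, index, g)
        x._accumulate(full)

    return Tensor._make(out_data, (x,), bw)


def pad2d(x: Tensor, pad: int | tuple[int, int]) -> Tensor:
    """Zero-pad the trailing two (spatial) axes of a (..., H, W) tensor."""
    ph, pw = (pad, pad) if isinstance(pad, int) else pad
    if ph == 0 and pw == 0:
        return x
    widths = [(0, 0)] * (x.ndim - 2) + [(ph, ph), (pw, pw)]
    out_data = np.pad(x.data, widths)

    def bw(g):
        sl = [slice(None)] * (x.ndim - 2) + [slice(ph, g.shape[-2] - ph),
                                             slice(pw, g.shape[-1] - pw)]
        x._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, (x,), bw)


def spatial_matmul(x: Tensor, mh: np.ndarray, mw: np.ndarray) -> Tensor:
    """Apply fixed row/column mixing matrices to a (B, C, H, W) tensor.

    Computes ``y[b,c] = mh @ x[b,c] @ mw.T`` — the workhorse behind bilinear
    resizing and adaptive average pooling, both of which are linear maps in
    the pixel values with precomputable coefficients.
    """
    mh = np.asarray(mh, dtype=np.float32)
    mw = np.asarray(mw, dtype=np.float32)
    out_data = np.einsum("oh,bchw,pw->bcop", mh, x.data, mw, optimize=True)

    def bw(g):
        x._accumulate(np.einsum("oh,bcop,pw->bchw", mh, g, mw, optimize=True))

    return Tensor._make(out_data, (x,), bw)


def where_const(cond: np.ndarray, x: Tensor, const: float) -> Tensor:
    """Elementwise ``cond ? x : const`` with a constant else-branch."""
    cond = np.asarray(cond, dtype=bool)
    out_data = np.where(cond, x.data, np.float32(const))

    def bw(g):
        x._accumulate(g * cond)

    return Tensor._make(out_data, (x,), bw)
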