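"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Just enough machinery for a 3D vision-transformer encoder-decoder: tensor
ops record a graph of closures, ``Tensor.backward()`` walks it in reverse
topological order. Convolution is expressed through an ``unfold3d`` gather
(im2col) plus matrix multiplication so the heavy lifting stays in BLAS.

Gradient correctness for every primitive is pinned by finite-difference
tests; the engine is deliberately minimal (no broadcasting corner cases
beyond what the network uses, batch dimension handled by the caller).
"""
from __future__ import annotations

import contextlib

import numpy as np
from scipy.special import erf as _erf

__all__ = ["Tensor", "Parameter", "no_grad", "cat", "softmax", "unfold3d"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _recording(*tensors):
    return _GRAD_ENABLED[-1] and any(t.requires_grad for t in tensors)


def _unbroadcast(grad, shape):
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _recording(*parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.requires_grad:
            g = np.asarray(g)
            self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # iterative topological sort (a recursive closure would both overflow
        # on deep graphs and create a reference cycle pinning every
        # intermediate array until the next gc pass)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            t, expanded = stack.pop()
            if expanded:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._prev:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bwd(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bwd)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.data.shape

        def bwd(g):
            self._accum(g.reshape(src))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(self.data.transpose(axes)), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bwd)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.data.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- pointwise nonlinearities -----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), bwd)

    def gelu(self):
        """Exact GELU: x * Phi(x) with Phi the standard normal CDF."""
        x = self.data
        phi = 0.5 * (1.0 + _erf(x / np.sqrt(2.0)))

        def bwd(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accum(g * (phi + x * pdf))

        return Tensor._make(x * phi, (self,), bwd)

    def clip_min(self, floor: float):
        """max(x, floor); gradient is zero where the floor is active."""
        mask = self.data > floor

        def bwd(g):
            self._accum(g * mask)

        return Tensor._make(np.maximum(self.data, floor), (self,), bwd)


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax as a primitive with its known backward."""
    x = t.data
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        t._accum(s * (g - dot))

    return Tensor._make(s, (t,), bwd)


def cat(tensors, axis: int = 0) -> Tensor:
    """Concatenate along an axis; backward splits the gradient."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def unfold3d(t: Tensor, k: int, pad: int) -> Tensor:
    """im2col for a (C, D, H, W) tensor with a cubic k-kernel and zero padding.

    Returns shape ``(C*k^3, D*H*W)`` (channels-first layout, so no permuted
    copy is needed). Backward scatter-adds each of the k^3 shifted slices
    back into the input.
    """
    C, D, H, W = t.data.shape
    xp = np.pad(t.data, ((0, 0), (pad, pad), (pad, pad), (pad, pad)))
    cols = np.empty((C, k * k * k, D, H, W), dtype=t.data.dtype)
    j = 0
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                cols[:, j] = xp[:, dz : dz + D, dy : dy + H, dx : dx + W]
                j += 1
    out = cols.reshape(C * k**3, D * H * W)

    def bwd(g):
        gc = g.reshape(C, k * k * k, D, H, W)
        gxp = np.zeros_like(xp)
        j = 0
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gxp[:, dz : dz + D, dy : dy + H, dx : dx + W] += gc[:, j]
                    j += 1
        if pad:
            gxp = gxp[:, pad:-pad, pad:-pad, pad:-pad]
        t._accum(gxp)

    return Tensor._make(out, (t,), bwd)
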