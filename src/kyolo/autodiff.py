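"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives a small convolutional detector
needs: broadcast-aware arithmetic, pointwise nonlinearities, reductions,
batched matmul, 2-D convolution (dense and depthwise), max-pooling,
nearest-neighbour upsampling, batch normalisation, concatenation and
indexing. Convolution is evaluated tap-by-tap (one batched matrix product
per kernel offset) so both the forward and the data/weight gradients run
through BLAS without materialising an im2col buffer.

Tensors are float32 by default and dtype-preserving (float64 in, float64
through — useful for finite-difference gradient checks). Gradients
accumulate into ``Tensor.grad`` after ``Tensor.backward()``; graph
construction can be suspended with :func:`no_grad` for inference.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "conv2d",
    "max_pool2d",
    "upsample_nearest2x",
    "batch_norm",
]

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


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        if isinstance(data, Tensor):
            data = data.data
        # float32 by default; float64 inputs keep their precision (useful for
        # gradient checks and geometry), integers are promoted to float32
        dt = np.float64 if getattr(data, "dtype", None) == np.float64 else np.float32
        self.data = np.asarray(data, dtype=dt)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"]) -> "Tensor":
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out = Tensor(data, requires_grad=True, _prev=tuple(parents))
        else:
            out = Tensor(data)
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype).copy()
        else:
            self.grad += grad

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs get deep during training
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and node._prev:
                # free intermediate grads? keep: cheap enough at our scale
                pass

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data + other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.data.shape))
            out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data - other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g, other.data.shape))
            out._backward = _bw
        return out

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data * other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.data.shape))
            out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data / other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data**2,
                                              other.data.shape))
            out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p):
        if isinstance(p, Tensor):
            raise TypeError("exponent must be a Python scalar")
        out = Tensor._make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor._make(e, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor._make(r, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / r)
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,))
        if out.requires_grad:
            s = np.sign(self.data)
            out._backward = lambda g: self._accum(g * s)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor._make(s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor._make(self.data * s, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 + self.data * (1.0 - s)))
        return out

    def hardswish(self):
        x = self.data
        y = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, x, x * (x + 3.0) / 6.0))
        out = Tensor._make(y.astype(x.dtype), (self,))
        if out.requires_grad:
            d = np.where(x <= -3.0, 0.0, np.where(x >= 3.0, 1.0, (2.0 * x + 3.0) / 6.0))
            out._backward = lambda g: self._accum(g * d.astype(x.dtype))
        return out

    def relu(self):
        out = Tensor._make(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:
            m = (self.data > 0).astype(self.data.dtype)
            out._backward = lambda g: self._accum(g * m)
        return out

    def clamp(self, lo=None, hi=None):
        y = np.clip(self.data, lo, hi)
        out = Tensor._make(y, (self,))
        if out.requires_grad:
            m = np.ones_like(self.data)
            if lo is not None:
                m = m * (self.data >= lo)
            if hi is not None:
                m = m * (self.data <= hi)
            out._backward = lambda g: self._accum(g * m)
        return out

    def maximum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(np.maximum(self.data, other.data), (self, other))
        if out.requires_grad:
            m = (self.data >= other.data).astype(self.data.dtype)  # ties -> first arg
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * m, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * (1.0 - m), other.data.shape))
            out._backward = _bw
        return out

    def minimum(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(np.minimum(self.data, other.data), (self, other))
        if out.requires_grad:
            m = (self.data <= other.data).astype(self.data.dtype)
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * m, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * (1.0 - m), other.data.shape))
            out._backward = _bw
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def _bw(g):
                gg = g
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))
            out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)
        out = Tensor._make(out_data, (self,))
        if out.requires_grad:
            def _bw(g):
                gg = g if keepdims else np.expand_dims(g, axis)
                grad = np.zeros_like(self.data)
                np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
                self._accum(grad)
            out._backward = _bw
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = Tensor._make(self.data[key], (self,))
        if out.requires_grad:
            def _bw(g):
                grad = np.zeros_like(self.data)
                np.add.at(grad, key, g)
                self._accum(grad)
            out._backward = _bw
        return out

    def matmul(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def _bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                             self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                              other.data.shape))
            out._backward = _bw
        return out

    __matmul__ = matmul


# -- free functions ------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def _bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = _bw
    return out


def _pad2d(x: np.ndarray, p: int, value: float = 0.0) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=value)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout.

    ``w`` has shape (c_out, c_in // groups, kh, kw). Dense (groups=1) and
    depthwise (groups == c_in == c_out) paths are specialised; other group
    counts fall back to a per-group dense loop.
    """
    B, Cin, H, W = x.data.shape
    Cout, Cg, kh, kw = w.data.shape
    xp = _pad2d(x.data, padding)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    out_data = np.zeros((B, Cout, Ho, Wo), dtype=x.data.dtype)

    def tap_view(arr, p, q):
        return arr[:, :, p:p + stride * Ho:stride, q:q + stride * Wo:stride]

    depthwise = groups == Cin and Cout == Cin and Cg == 1
    if depthwise:
        for p in range(kh):
            for q in range(kw):
                out_data += tap_view(xp, p, q) * w.data[:, 0, p, q][None, :, None, None]
    elif groups == 1:
        o2 = out_data.reshape(B, Cout, Ho * Wo)
        for p in range(kh):
            for q in range(kw):
                xs = np.ascontiguousarray(tap_view(xp, p, q)).reshape(B, Cin, Ho * Wo)
                o2 += np.matmul(w.data[:, :, p, q][None], xs)
    else:
        cg_in = Cin // groups
        cg_out = Cout // groups
        for gi in range(groups):
            xi = xp[:, gi * cg_in:(gi + 1) * cg_in]
            o2 = out_data[:, gi * cg_out:(gi + 1) * cg_out].reshape(B, cg_out, Ho * Wo)
            for p in range(kh):
                for q in range(kw):
                    xs = np.ascontiguousarray(tap_view(xi, p, q)).reshape(B, cg_in, Ho * Wo)
                    o2 += np.matmul(w.data[gi * cg_out:(gi + 1) * cg_out, :, p, q][None], xs)
        out_data = out_data.reshape(B, Cout, Ho, Wo)

    if b is not None:
        out_data += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents)
    if out.requires_grad:
        def _bw(g):
            g = np.ascontiguousarray(g)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            need_x = x.requires_grad
            need_w = w.requires_grad
            dxp = np.zeros_like(xp) if need_x else None
            dw = np.zeros_like(w.data) if need_w else None
            g2 = g.reshape(B, Cout, Ho * Wo)
            if depthwise:
                for p in range(kh):
                    for q in range(kw):
                        xs = tap_view(xp, p, q)
                        if need_w:
                            dw[:, 0, p, q] += (g * xs).sum(axis=(0, 2, 3))
                        if need_x:
                            tap_view(dxp, p, q)[...] += g * w.data[:, 0, p, q][None, :, None, None]
            elif groups == 1:
                for p in range(kh):
                    for q in range(kw):
                        xs = np.ascontiguousarray(tap_view(xp, p, q)).reshape(B, Cin, Ho * Wo)
                        if need_w:
                            dw[:, :, p, q] += np.matmul(g2, xs.transpose(0, 2, 1)).sum(axis=0)
                        if need_x:
                            dxs = np.matmul(w.data[:, :, p, q].T[None], g2)
                            tap_view(dxp, p, q)[...] += dxs.reshape(B, Cin, Ho, Wo)
            else:
                cg_in = Cin // groups
                cg_out = Cout // groups
                for gi in range(groups):
                    sl_in = slice(gi * cg_in, (gi + 1) * cg_in)
                    sl_out = slice(gi * cg_out, (gi + 1) * cg_out)
                    gg = g2[:, sl_out]
                    for p in range(kh):
                        for q in range(kw):
                            xs = np.ascontiguousarray(
                                tap_view(xp[:, sl_in], p, q)).reshape(B, cg_in, Ho * Wo)
                            if need_w:
                                dw[sl_out, :, p, q] += np.matmul(
                                    gg, xs.transpose(0, 2, 1)).sum(axis=0)
                            if need_x:
                                dxs = np.matmul(w.data[sl_out, :, p, q].T[None], gg)
                                tap_view(dxp[:, sl_in], p, q)[...] += dxs.reshape(
                                    B, cg_in, Ho, Wo)
            if need_w:
                w._accum(dw)
            if need_x:
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accum(dxp)
        out._backward = _bw
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    B, C, H, W = x.data.shape
    xp = _pad2d(x.data, padding, value=-np.inf)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kernel) // stride + 1
    Wo = (Wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,k,k)
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    idx = np.argmax(flat, axis=-1)
    out = Tensor._make(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], (x,))
    if out.requires_grad:
        def _bw(g):
            dxp = np.zeros_like(xp)
            ki, kj = np.divmod(idx, kernel)
            bi, ci, oi, oj = np.indices(idx.shape, sparse=False)
            rows = oi * stride + ki
            cols = oj * stride + kj
            np.add.at(dxp, (bi, ci, rows, cols), g)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
        out._backward = _bw
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    y = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    out = Tensor._make(y, (x,))
    if out.requires_grad:
        B, C, H, W = x.data.shape
        def _bw(g):
            x._accum(g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))
        out._backward = _bw
    return out


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               momentum: float = 0.03, eps: float = 1e-3,
               training: bool = True) -> Tensor:
    """Batch normalisation over (B, H, W) per channel, NCHW layout.

    ``running_mean`` / ``running_var`` are plain arrays updated in place in
    training mode (YOLOv5-style momentum convention: new = (1-m)*old + m*batch).
    """
    B, C, H, W = x.data.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = B * H * W
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mean
        running_var *= (1.0 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mean = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor._make(y.astype(x.data.dtype), (x, gamma, beta))
    if out.requires_grad:
        def _bw(g):
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
                if training:
                    n = B * H * W
                    gs = g.sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
                    gxs = (g * xhat).sum(axis=(0, 2, 3), keepdims=True).transpose(1, 0, 2, 3)
                    dx = gi * (g - gs.transpose(1, 0, 2, 3) / n
                               - xhat * gxs.transpose(1, 0, 2, 3) / n)
                else:
                    dx = gi * g
                x._accum(dx.astype(x.data.dtype))
        out._backward = _bw
    return out
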