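"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records, per operation, a
closure that propagates gradients to its parents.  The op set is exactly
what an encoder--decoder segmentation network and its losses need:
elementwise arithmetic, activations, reductions, 2-D (dilated) convolution,
depthwise convolution, batch normalisation, bilinear resizing, padding-free
concatenation and broadcasting.  Everything is eager and single-threaded;
``no_grad()`` disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _track(*tensors: "Tensor") -> bool:
    return _GRAD_ENABLED and any(t.requires_grad or t._parents for t in tensors)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        # float32 is the working precision; explicit float64 arrays are
        # preserved so closed-form loss values can be checked tightly
        if (isinstance(data, (np.ndarray, np.generic))
                and data.dtype == np.float64):
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this tensor (seeded with ones)."""
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
            if node._parents:  # free intermediates
                node._backward = None

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _track(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise ------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data / b.data

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(data, (a, b), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def power(a, exponent: float) -> Tensor:
    """Elementwise ``a ** exponent`` for a scalar exponent >= 0."""
    a = as_tensor(a)
    data = np.power(a.data, exponent)

    def backward(g):
        if exponent == 0:
            a._accumulate(np.zeros_like(a.data))
        else:
            a._accumulate(g * exponent * np.power(a.data, exponent - 1))

    return _make(data, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    a = as_tensor(a)
    data = np.clip(a.data, lo, hi)

    def backward(g):
        mask = (a.data >= lo) & (a.data <= hi)
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(data, (a,), backward)


def relu6(a) -> Tensor:
    a = as_tensor(a)
    data = np.clip(a.data, 0, 6)

    def backward(g):
        a._accumulate(g * ((a.data > 0) & (a.data < 6)))

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * y * (1.0 - y))

    return _make(y, (a,), backward)


def softmax(a, axis: int = 1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        a._accumulate(y * (g - dot))

    return _make(y, (a,), backward)


# -- reductions / shape ----------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reduce_max(a, axis, keepdims: bool = True) -> Tensor:
    a = as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)

    def backward(g):
        full = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == full).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(mask * g)

    return _make(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _make(data, (a,), backward)


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    data = np.broadcast_to(a.data, shape).copy()

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))

    return _make(data, (a,), backward)


def concat(tensors: Sequence, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(offset, offset + s)
            t._accumulate(g[tuple(idx)])
            offset += s

    return _make(data, tuple(tensors), backward)


# -- convolution ------------------------------------------------------

def _out_size(size: int, k: int, stride: int, pad: int, dilation: int) -> int:
    return (size + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            dilation: int) -> tuple[np.ndarray, int, int]:
    b, c, h, w = x.shape
    oh = _out_size(h, kh, stride, pad, dilation)
    ow = _out_size(w, kw, stride, pad, dilation)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    sb, sc, sh, sw = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(b, c, kh, kw, oh, ow),
        strides=(sb, sc, sh * dilation, sw * dilation, sh * stride, sw * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(view).reshape(b, c * kh * kw, oh * ow)
    return cols, oh, ow


def _col2im(gcols: np.ndarray, x_shape: tuple, kh: int, kw: int, stride: int,
            pad: int, dilation: int, oh: int, ow: int) -> np.ndarray:
    b, c, h, w = x_shape
    gxp = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    g6 = gcols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            gxp[:, :, hi:hi + stride * oh:stride,
                wj:wj + stride * ow:stride] += g6[:, :, i, j]
    if pad:
        return gxp[:, :, pad:-pad, pad:-pad]
    return gxp


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, groups == 1."""
    x, w = as_tensor(x), as_tensor(w)
    cout, cin, kh, kw = w.data.shape
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding, dilation)
    w2 = w.data.reshape(cout, -1)
    out = np.matmul(w2, cols).reshape(x.data.shape[0], cout, oh, ow)
    if b is not None:
        b = as_tensor(b)
        out += b.data.reshape(1, cout, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2 = g.reshape(g.shape[0], cout, oh * ow)
        w._accumulate(np.tensordot(g2, cols, axes=([0, 2], [0, 2])).reshape(w.data.shape))
        gcols = np.matmul(w2.T, g2)
        x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, padding,
                              dilation, oh, ow))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out, parents, backward)


def depthwise_conv2d(x, w, stride: int = 1, padding: int = 0,
                     dilation: int = 1) -> Tensor:
    """Depthwise convolution: one k x k filter per channel (weight C x k x k)."""
    x, w = as_tensor(x), as_tensor(w)
    c, kh, kw = w.data.shape
    b, cx, h, ww_ = x.data.shape
    if cx != c:
        raise ValueError(f"channel mismatch: input {cx}, weight {c}")
    oh = _out_size(h, kh, stride, padding, dilation)
    ow = _out_size(ww_, kw, stride, padding, dilation)
    xp = (np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
          if padding else x.data)
    out = np.zeros((b, c, oh, ow), dtype=np.float32)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            patch = xp[:, :, hi:hi + stride * oh:stride, wj:wj + stride * ow:stride]
            out += w.data[:, i, j].reshape(1, c, 1, 1) * patch

    def backward(g):
        gw = np.zeros_like(w.data)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            hi = i * dilation
            for j in range(kw):
                wj = j * dilation
                patch = xp[:, :, hi:hi + stride * oh:stride,
                           wj:wj + stride * ow:stride]
                gw[:, i, j] = (g * patch).sum(axis=(0, 2, 3))
                gxp[:, :, hi:hi + stride * oh:stride,
                    wj:wj + stride * ow:stride] += w.data[:, i, j].reshape(1, c, 1, 1) * g
        w._accumulate(gw)
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)

    return _make(out, (x, w), backward)


# -- bilinear resize --------------------------------------------------

_RESIZE_CACHE: dict[tuple, sp.csr_matrix] = {}


def _resize_matrix(ih: int, iw: int, oh: int, ow: int) -> sp.csr_matrix:
    """Sparse (oh*ow, ih*iw) bilinear interpolation operator.

    Half-pixel (align_corners=False) source mapping with edge clamping.
    """
    key = (ih, iw, oh, ow)
    m = _RESIZE_CACHE.get(key)
    if m is not None:
        return m
    oy = (np.arange(oh, dtype=np.float64) + 0.5) * (ih / oh) - 0.5
    ox = (np.arange(ow, dtype=np.float64) + 0.5) * (iw / ow) - 0.5
    y0 = np.clip(np.floor(oy), 0, ih - 1).astype(np.int64)
    x0 = np.clip(np.floor(ox), 0, iw - 1).astype(np.int64)
    y1 = np.minimum(y0 + 1, ih - 1)
    x1 = np.minimum(x0 + 1, iw - 1)
    wy = np.clip(oy - y0, 0.0, 1.0)
    wx = np.clip(ox - x0, 0.0, 1.0)

    rows, cols, vals = [], [], []
    out_idx = np.arange(oh * ow).reshape(oh, ow)
    for ys, wys in ((y0, 1.0 - wy), (y1, wy)):
        for xs, wxs in ((x0, 1.0 - wx), (x1, wx)):
            rows.append(out_idx.ravel())
            cols.append((ys[:, None] * iw + xs[None, :]).ravel())
            vals.append((wys[:, None] * wxs[None, :]).ravel())
    m = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(oh * ow, ih * iw), dtype=np.float32,
    )
    m.sum_duplicates()
    _RESIZE_CACHE[key] = m
    return m


def bilinear_resize(x, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resize of NCHW tensors to ``out_hw`` (half-pixel convention)."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    m = _resize_matrix(h, w, oh, ow)
    flat = x.data.reshape(b * c, h * w)
    out = (m @ flat.T).T.reshape(b, c, oh, ow)

    def backward(g):
        gflat = g.reshape(b * c, oh * ow)
        x._accumulate((m.T @ gflat.T).T.reshape(b, c, h, w))

    return _make(out, (x,), backward)


def bilinear_resize_array(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Plain-ndarray bilinear resize of an H x W (x C) image, same convention."""
    arr = np.asarray(img, dtype=np.float32)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    h, w, c = arr.shape
    m = _resize_matrix(h, w, *out_hw)
    out = (m @ arr.reshape(h * w, c)).reshape(out_hw[0], out_hw[1], c)
    return out[:, :, 0] if squeeze else out


# -- batch normalisation ----------------------------------------------

def batch_norm(x, gamma, beta, running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    c = x.data.shape[1]
    shape = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        unbiased = var * (n / max(n - 1, 1))
        running_var *= 1 - momentum
        running_var += momentum * unbiased
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gs = gamma.data.reshape(shape) * inv_std.reshape(shape)
        if training:
            gm = g.mean(axis=(0, 2, 3), keepdims=True)
            gxm = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accumulate(gs * (g - gm - xhat * gxm))
        else:
            x._accumulate(gs * g)

    return _make(out, (x, gamma, beta), backward)
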