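"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation network needs: broadcasted
arithmetic, matmul, stride-1 (dilated, optionally depthwise) 2-D convolution,
the pooling variants used by the encoder, channel/batch normalization,
bilinear x2 upsampling with half-pixel centers, and the pointwise
nonlinearities.  All tensors are float32; spatial activations are laid out
channel-last (N, H, W, C) so convolutions run as strided stacked GEMMs with
no transposition copies.  Layout-conversion ops bridge to the channel-first
public interface.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True

# When not None, conv/linear forward passes add their multiply-accumulate
# counts here (used by the complexity counter).
_MAC_COUNTER: list | None = None


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


@contextlib.contextmanager
def count_macs_into(counter: list):
    """Within this context, conv/linear ops append their MAC counts to ``counter``."""
    global _MAC_COUNTER
    prev = _MAC_COUNTER
    _MAC_COUNTER = counter
    try:
        yield
    finally:
        _MAC_COUNTER = prev



_ONES_CACHE: dict = {}


def _ones(n: int) -> np.ndarray:
    v = _ONES_CACHE.get(n)
    if v is None:
        v = np.ones(n, dtype=np.float32)
        _ONES_CACHE[n] = v
    return v


def _sum_to_c(a: np.ndarray) -> np.ndarray:
    """Sum an (..., C) array over all leading axes via a BLAS GEMV."""
    a2 = a.reshape(-1, a.shape[-1])
    return _ones(a2.shape[0]) @ a2


def _dot_to_c(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sum over leading axes of a*b, per channel (last axis)."""
    return _sum_to_c(a * b)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # free graph references as we go
            t._backward = None
            t._prev = ()

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    parents = [p for p in parents if isinstance(p, Tensor)]
    if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = False
        out._prev = tuple(parents)
        out._backward = backward
        # mark as graph-internal so descendants keep linking
        out.requires_grad = any(p.requires_grad for p in parents) or True
    return out


def _accum(t: Tensor, g: np.ndarray, own: bool = False):
    """Accumulate gradient ``g`` into ``t``.

    ``own=True`` promises that ``g`` is a freshly allocated array not shared
    with any other consumer, allowing assignment without a defensive copy.
    """
    if t.grad is None:
        if own and g.dtype == np.float32:
            t.grad = g
        else:
            t.grad = np.array(g, dtype=np.float32)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(np.float32, copy=False)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        ga = _unbroadcast(g, a.shape)
        _accum(a, ga, own=ga is not g)
        gb = _unbroadcast(g, b.shape)
        _accum(b, gb, own=gb is not g)

    return _node(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._prev:
            _accum(a, _unbroadcast(g * b.data, a.shape), own=True)
        if b.requires_grad or b._prev:
            _accum(b, _unbroadcast(g * a.data, b.shape), own=True)

    return _node(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._prev:
            _accum(a, _unbroadcast(g / b.data, a.shape), own=True)
        if b.requires_grad or b._prev:
            _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape), own=True)

    return _node(out_data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        _accum(a, g.reshape(old))

    return _node(out_data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None:
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
        _accum(a, np.broadcast_to(g, a.shape).astype(np.float32), own=True)

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data
    if _MAC_COUNTER is not None:
        _MAC_COUNTER.append(int(np.prod(out_data.shape)) * a.shape[-1])

    def backward(g):
        if a.requires_grad or a._prev:
            _accum(a, g @ b.data.T, own=True)
        if b.requires_grad or b._prev:
            _accum(b, a.data.T @ g, own=True)

    return _node(out_data, (a, b), backward)


def concat(tensors, axis=1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, np.ascontiguousarray(g[tuple(sl)]), own=True)

    return _node(out_data, tensors, backward)


# ---------------------------------------------------------------------------
# pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        _accum(a, g * (a.data > 0), own=True)

    return _node(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    out_data = sigmoid_np(a.data)

    def backward(g):
        _accum(a, g * out_data * (1.0 - out_data), own=True)

    return _node(out_data, (a,), backward)


def sigmoid_np(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


_INV_SQRT2 = np.float32(1.0 / np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


def gelu(a) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    a = as_tensor(a)
    x = a.data
    cdf = 0.5 * (1.0 + erf(x * _INV_SQRT2))
    out_data = (x * cdf).astype(np.float32)

    def backward(g):
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        _accum(a, (g * (cdf + x * pdf)).astype(np.float32, copy=False), own=True)

    return _node(out_data, (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + exp(x)), evaluated stably; derivative is sigmoid(x)."""
    a = as_tensor(a)
    x = a.data
    out_data = (np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))).astype(np.float32)

    def backward(g):
        _accum(a, g * sigmoid_np(x), own=True)

    return _node(out_data, (a,), backward)


def softmax(a, axis=1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot), own=True)

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# spatial ops (NHWC layout)
#
# All spatial operations below take activations laid out (N, H, W, C); the
# channel-last layout lets convolutions run as strided stacked GEMMs without
# any transposition copies.  Convolution weights keep the conventional
# (Cout, Cin, k, k) layout.  The layout-conversion ops at the end bridge to
# the public channel-first interface.
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, dilation: int = 1) -> Tensor:
    """Stride-1 2-D convolution with 'same' padding (pad = dilation*(k-1)/2).

    x: (N, H, W, Cin); w: (Cout, Cin, k, k); b: (Cout,) or None.
    Evaluated as one stacked GEMM per kernel tap directly on strided views.
    """
    x = as_tensor(x)
    w = as_tensor(w)
    n, h, wd, cin = x.shape
    cout, cin_w, k, _ = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: expected {cin_w} input channels, received {cin}")
    pad = dilation * (k - 1) // 2

    if _MAC_COUNTER is not None:
        _MAC_COUNTER.append(cout * h * wd * cin * k * k * n)

    wtap = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0))  # (k, k, Cin, Cout)

    if k == 1:
        out_data = np.matmul(x.data, wtap[0, 0])
        if b is not None:
            out_data += b.data

        def backward1(g):
            g2 = g.reshape(-1, cout)
            x2 = x.data.reshape(-1, cin)
            if w.requires_grad or w._prev:
                _accum(w, (x2.T @ g2).T.reshape(cout, cin, 1, 1), own=True)
            if b is not None:
                _accum(b, _sum_to_c(g), own=True)
            if x.requires_grad or x._prev:
                _accum(x, (g2 @ wtap[0, 0].T).reshape(x.shape), own=True)

        parents = (x, w, b) if b is not None else (x, w)
        return _node(out_data, parents, backward1)

    xq = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    d = dilation
    out_data = None
    for i in range(k):
        for j in range(k):
            sl = xq[:, i * d:i * d + h, j * d:j * d + wd, :]
            r = np.matmul(sl, wtap[i, j])
            out_data = r if out_data is None else out_data.__iadd__(r)
    if b is not None:
        out_data += b.data

    def backward(g):
        if w.requires_grad or w._prev:
            dw = np.empty_like(wtap)
            for i in range(k):
                for j in range(k):
                    sl = xq[:, i * d:i * d + h, j * d:j * d + wd, :]
                    # stacked (C, W) @ (W, Cout) per (n, h) row, then reduce
                    dw[i, j] = np.matmul(sl.transpose(0, 1, 3, 2), g).sum(axis=(0, 1))
            _accum(w, np.ascontiguousarray(dw.transpose(3, 2, 0, 1)), own=True)
        if b is not None:
            _accum(b, _sum_to_c(g), own=True)
        if x.requires_grad or x._prev:
            gxq = np.zeros_like(xq)
            for i in range(k):
                for j in range(k):
                    gxq[:, i * d:i * d + h, j * d:j * d + wd, :] += np.matmul(
                        g, wtap[i, j].T)
            gx = gxq[:, pad:-pad, pad:-pad, :] if pad else gxq
            _accum(x, np.ascontiguousarray(gx), own=True)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out_data, parents, backward)


def depthwise_conv2d(x, w, b=None) -> Tensor:
    """Per-channel convolution. x: (N, H, W, C); w: (C, k, k)."""
    x = as_tensor(x)
    w = as_tensor(w)
    n, h, wd, c = x.shape
    cw, k, _ = w.shape
    if c != cw:
        raise ValueError(f"depthwise_conv2d: expected {cw} channels, received {c}")
    pad = (k - 1) // 2
    if _MAC_COUNTER is not None:
        _MAC_COUNTER.append(c * h * wd * k * k * n)
    xq = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    out_data = None
    for i in range(k):
        for j in range(k):
            r = xq[:, i:i + h, j:j + wd, :] * w.data[:, i, j]
            out_data = r if out_data is None else out_data.__iadd__(r)
    if b is not None:
        out_data += b.data

    def backward(g):
        dw = np.empty_like(w.data)
        gxq = np.zeros_like(xq)
        for i in range(k):
            for j in range(k):
                dw[:, i, j] = _dot_to_c(g, xq[:, i:i + h, j:j + wd, :])
                gxq[:, i:i + h, j:j + wd, :] += g * w.data[:, i, j]
        _accum(w, dw, own=True)
        if b is not None:
            _accum(b, _sum_to_c(g), own=True)
        if x.requires_grad or x._prev:
            gx = gxq[:, pad:-pad, pad:-pad, :] if pad else gxq
            _accum(x, np.ascontiguousarray(gx), own=True)

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out_data, parents, backward)


def linear(x, w, b=None) -> Tensor:
    """x: (N, Fin); w: (Fout, Fin); b: (Fout,)."""
    out = matmul(x, transpose2d(w))
    if b is not None:
        out = add(out, b)
    return out


def transpose2d(a) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.T

    def backward(g):
        _accum(a, g.T)

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# pooling and resampling (NHWC)
# ---------------------------------------------------------------------------

def maxpool3x3_s1(x) -> Tensor:
    """3x3 window, stride 1, padding 1 (shape preserving) max pooling.

    Gradient is distributed to every position attaining the window maximum.
    """
    x = as_tensor(x)
    n, h, w, c = x.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
    out_data = None
    for i in range(3):
        for j in range(3):
            sl = xp[:, i:i + h, j:j + w, :]
            out_data = sl.copy() if out_data is None else np.maximum(out_data, sl, out=out_data)

    def backward(g):
        gxp = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                sl = xp[:, i:i + h, j:j + w, :]
                gxp[:, i:i + h, j:j + w, :] += g * (sl == out_data)
        _accum(x, np.ascontiguousarray(gxp[:, 1:-1, 1:-1, :]), own=True)

    return _node(out_data, (x,), backward)


def maxpool2x2(x) -> Tensor:
    """2x2 stride-2 max pooling; H and W must be even."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out_data = xr.max(axis=(2, 4))

    def backward(g):
        mask = xr == out_data[:, :, None, :, None, :]
        gx = mask * g[:, :, None, :, None, :]
        _accum(x, np.ascontiguousarray(gx.reshape(n, h, w, c)), own=True)

    return _node(out_data, (x,), backward)


def avgpool2x2(x) -> Tensor:
    x = as_tensor(x)
    n, h, w, c = x.shape
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out_data = xr.mean(axis=(2, 4))

    def backward(g):
        gx = np.broadcast_to(g[:, :, None, :, None, :] * 0.25, xr.shape)
        _accum(x, gx.reshape(n, h, w, c).astype(np.float32), own=True)

    return _node(out_data, (x,), backward)


def global_avg_pool(x) -> Tensor:
    """(N, H, W, C) -> (N, C)."""
    return tmean(x, axis=(1, 2))


def _up2_axis1(a: np.ndarray) -> np.ndarray:
    """1-D x2 bilinear upsampling along axis 1, half-pixel centers.

    out[2i]   = 0.25*in[i-1] + 0.75*in[i]   (i >= 1), out[0] = in[0]
    out[2i+1] = 0.75*in[i]   + 0.25*in[i+1] (i <= m-2), out[2m-1] = in[m-1]
    """
    m = a.shape[1]
    even = 0.75 * a
    even[:, 0] += 0.25 * a[:, 0]
    even[:, 1:] += 0.25 * a[:, :-1]
    odd = 0.75 * a
    odd[:, -1] += 0.25 * a[:, -1]
    odd[:, :-1] += 0.25 * a[:, 1:]
    out = np.empty((a.shape[0], 2 * m) + a.shape[2:], dtype=a.dtype)
    out[:, 0::2] = even
    out[:, 1::2] = odd
    return out


def _up2_axis1_adjoint(g: np.ndarray) -> np.ndarray:
    ge = np.ascontiguousarray(g[:, 0::2])
    go = np.ascontiguousarray(g[:, 1::2])
    out = 0.75 * ge
    out[:, 0] += 0.25 * ge[:, 0]
    out[:, :-1] += 0.25 * ge[:, 1:]
    out += 0.75 * go
    out[:, -1] += 0.25 * go[:, -1]
    out[:, 1:] += 0.25 * go[:, :-1]
    return out


def _swap12(a: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(a.transpose(0, 2, 1, 3))


def upsample_bilinear2x(x) -> Tensor:
    """x2 bilinear upsampling (NHWC) with half-pixel centers."""
    x = as_tensor(x)
    out_data = _swap12(_up2_axis1(_swap12(_up2_axis1(x.data))))

    def backward(g):
        gx = _up2_axis1_adjoint(_swap12(_up2_axis1_adjoint(_swap12(g))))
        _accum(x, gx, own=True)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# normalization (NHWC)
# ---------------------------------------------------------------------------

def batch_norm(x, gain, offset, running_mean, running_var, training: bool,
               momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel; x is (N, H, W, C).

    ``running_mean``/``running_var`` are plain numpy arrays mutated in place
    when ``training`` is true.
    """
    x = as_tensor(x)
    if training:
        n_eff = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
        s1 = _sum_to_c(x.data)
        s2 = _dot_to_c(x.data, x.data)
        mean = s1 / n_eff
        var = np.maximum(s2 / n_eff - mean * mean, 0.0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        unbiased = var * (n_eff / max(n_eff - 1, 1))
        running_var *= 1.0 - momentum
        running_var += momentum * unbiased
    else:
        mean = running_mean
        var = running_var
    invstd = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = (x.data - mean) * invstd
    out_data = gain.data * xhat + offset.data

    def backward(g):
        _accum(gain, _dot_to_c(g, xhat), own=True)
        _accum(offset, _sum_to_c(g), own=True)
        if not (x.requires_grad or x._prev):
            return
        gxh = g * gain.data
        if training:
            n_eff = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]
            t1 = _sum_to_c(gxh)
            t2 = _dot_to_c(gxh, xhat)
            gxh -= t1 / n_eff
            gxh -= xhat * (t2 / n_eff)
            gxh *= invstd
        else:
            gxh *= invstd
        _accum(x, gxh.astype(np.float32, copy=False), own=True)

    return _node(out_data.astype(np.float32, copy=False), (x, gain, offset), backward)


def layer_norm_channels(x, gain, offset, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the channel axis at each (n, h, w) location."""
    x = as_tensor(x)
    mean = x.data.mean(axis=3, keepdims=True)
    var = x.data.var(axis=3, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * invstd
    out_data = gain.data * xhat + offset.data

    def backward(g):
        _accum(gain, _dot_to_c(g, xhat), own=True)
        _accum(offset, _sum_to_c(g), own=True)
        gxh = g * gain.data
        c = x.data.shape[3]
        s1 = gxh.sum(axis=3, keepdims=True)
        s2 = (gxh * xhat).sum(axis=3, keepdims=True)
        gx = (gxh - s1 / c - xhat * s2 / c) * invstd
        _accum(x, gx.astype(np.float32, copy=False), own=True)

    return _node(out_data.astype(np.float32, copy=False), (x, gain, offset), backward)


# ---------------------------------------------------------------------------
# layout conversion
# ---------------------------------------------------------------------------

def nchw_to_nhwc(x) -> Tensor:
    x = as_tensor(x)
    out_data = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))

    def backward(g):
        _accum(x, np.ascontiguousarray(g.transpose(0, 3, 1, 2)), own=True)

    return _node(out_data, (x,), backward)


def nhwc_to_nchw(x) -> Tensor:
    x = as_tensor(x)
    out_data = np.ascontiguousarray(x.data.transpose(0, 3, 1, 2))

    def backward(g):
        _accum(x, np.ascontiguousarray(g.transpose(0, 2, 3, 1)), own=True)

    return _node(out_data, (x,), backward)
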