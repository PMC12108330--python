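"""Reverse-mode autodiff on numpy arrays.

A minimal tape-based engine providing exactly the operations the
segmentation network needs: broadcast arithmetic, matmul, dense/depthwise
2-D convolution (with stride, zero padding and dilation), pooling,
nearest/bilinear resampling, a 1-D convolution across the channel axis,
normalisation statistics, the activations used by the blocks, and softmax /
cross-entropy.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` via topological sort.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf


class Tensor:
    """N-d array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._prev:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _const(-1.0)))

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def item(self):
        return float(self.data)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _const(x) -> Tensor:
    return Tensor(np.asarray(x))


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._prev for p in parents):
        out._prev = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- elementwise / arithmetic -------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._prev:
            a._accum(_unbroadcast(g, a.shape))
        if b.requires_grad or b._prev:
            b._accum(_unbroadcast(g, b.shape))

    return _node(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._prev:
            a._accum(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._prev:
            b._accum(_unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1.0))

    return _node(data, (a,), backward)


def sqrt(a: Tensor) -> Tensor:
    return power(a, 0.5)


def exp(a: Tensor) -> Tensor:
    data = np.exp(a.data)

    def backward(g):
        a._accum(g * data)

    return _node(data, (a,), backward)


def log(a: Tensor) -> Tensor:
    data = np.log(a.data)

    def backward(g):
        a._accum(g / a.data)

    return _node(data, (a,), backward)


def relu6(a: Tensor) -> Tensor:
    data = np.clip(a.data, 0.0, 6.0)

    def backward(g):
        a._accum(g * ((a.data > 0) & (a.data < 6)).astype(a.dtype))

    return _node(data, (a,), backward)


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = a.data
    cdf = 0.5 * (1.0 + erf(x / _SQRT2))
    data = x * cdf

    def backward(g):
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
        a._accum((g * (cdf + x * pdf)).astype(a.dtype, copy=False))

    return _node(data.astype(a.dtype, copy=False), (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * data * (1.0 - data))

    return _node(data, (a,), backward)


# -- shape ops ----------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(old))

    return _node(data, (a,), backward)


def transpose(a: Tensor, axes=None) -> Tensor:
    data = a.data.transpose(axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        a._accum(g.transpose(inv))

    return _node(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._prev:
                t._accum(piece)

    return _node(data, tuple(tensors), backward)


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            ax = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, ax)
        a._accum(np.broadcast_to(g, a.shape).astype(a.dtype, copy=False))

    return _node(data, (a,), backward)


def mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(sum_(a, axis, keepdims), _const(1.0 / n))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._prev:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad or b._prev:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    return _node(data, (a, b), backward)


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        a._accum(data * (g - dot))

    return _node(data, (a,), backward)


# -- convolution --------------------------------------------------------------

def _im2col(x, kh, kw, stride, padding, dilation):
    """Return (cols, out_h, out_w); cols has shape (N, C*kh*kw, out_h*out_w)."""
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    win = sliding_window_view(x, (eh, ew), axis=(2, 3))
    win = win[:, :, ::stride, ::stride, ::dilation, ::dilation]
    out_h, out_w = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, out_h * out_w)
    return np.ascontiguousarray(cols), out_h, out_w


def _col2im(cols, x_shape, kh, kw, stride, padding, dilation, out_h, out_w):
    """Adjoint of ``_im2col`` (scatter-add patches back into an image)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    xp = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, out_h, out_w)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            xp[:, :, hi:hi + stride * out_h:stride, wj:wj + stride * out_w:stride] += cols[:, :, i, j]
    if padding:
        xp = xp[:, :, padding:-padding, padding:-padding]
    return xp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Dense 2-D convolution, NCHW layout, weight (C_out, C_in, kh, kw)."""
    co, ci, kh, kw = weight.shape
    if x.shape[1] != ci:
        raise ValueError(f"conv2d: input has {x.shape[1]} channels, weight expects {ci}")
    cols, out_h, out_w = _im2col(x.data, kh, kw, stride, padding, dilation)
    wmat = weight.data.reshape(co, ci * kh * kw)
    out = np.matmul(wmat, cols)  # (N, Co, out_h*out_w) via BLAS
    out = out.reshape(x.shape[0], co, out_h, out_w)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.reshape(g.shape[0], co, out_h * out_w))
        if weight.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            weight._accum(gw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gcols = np.matmul(wmat.T, gmat)
            x._accum(_col2im(gcols, x.shape, kh, kw, stride, padding,
                             dilation, out_h, out_w))

    return _node(out, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
                     stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """Per-channel 2-D convolution; weight (C, kh, kw)."""
    c, kh, kw = weight.shape
    if x.shape[1] != c:
        raise ValueError(f"depthwise_conv2d: {x.shape[1]} channels vs weight {c}")
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xd.shape[2], xd.shape[3]
    eh = (kh - 1) * dilation + 1
    ew = (kw - 1) * dilation + 1
    out_h = (hp - eh) // stride + 1
    out_w = (wp - ew) // stride + 1
    wdat = weight.data
    out = np.zeros((x.shape[0], c, out_h, out_w), dtype=xd.dtype)
    for i in range(kh):  # tap loop beats a 6-D einsum on strided views
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            out += xd[:, :, hi:hi + stride * out_h:stride,
                      wj:wj + stride * out_w:stride] * wdat[:, i, j].reshape(1, c, 1, 1)
    if bias is not None:
        out = out + bias.data.reshape(1, c, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            gw = np.empty((c, kh, kw), dtype=g.dtype)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    patch = xd[:, :, hi:hi + stride * out_h:stride,
                               wj:wj + stride * out_w:stride]
                    gw[:, i, j] = (patch * g).sum(axis=(0, 2, 3))
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            hp = x.shape[2] + 2 * padding
            wp = x.shape[3] + 2 * padding
            gx = np.zeros((x.shape[0], c, hp, wp), dtype=g.dtype)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gx[:, :, hi:hi + stride * out_h:stride,
                       wj:wj + stride * out_w:stride] += g * weight.data[:, i, j].reshape(1, c, 1, 1)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding]
            x._accum(gx)

    return _node(out, parents, backward)


def channel_conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """1-D convolution along the LAST axis with zero padding (odd kernel).

    Used for efficient channel attention: the last axis is the channel axis,
    all leading axes are broadcast positions.  weight shape (k,).
    """
    k = weight.shape[0]
    p = k // 2
    xp = np.pad(x.data, [(0, 0)] * (x.ndim - 1) + [(p, p)])
    win = sliding_window_view(xp, k, axis=-1)
    out = win @ weight.data
    if bias is not None:
        out = out + bias.data
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("...ck,...c->k", win, g, optimize=True)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(np.asarray(g.sum(), dtype=bias.dtype).reshape(bias.shape))
        if x.requires_grad or x._prev:
            gp = np.pad(g, [(0, 0)] * (g.ndim - 1) + [(p, p)])
            gwin = sliding_window_view(gp, k, axis=-1)
            x._accum(gwin @ weight.data[::-1])

    return _node(out, parents, backward)


# -- pooling & resampling -----------------------------------------------------

def maxpool2d(x: Tensor, size: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % size or w % size:
        raise ValueError(f"maxpool2d: spatial dims {(h, w)} not divisible by {size}")
    v = x.data.reshape(n, c, h // size, size, w // size, size)
    v = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // size, w // size, size * size)
    idx = v.argmax(axis=-1)
    out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gv = np.zeros_like(v)
        np.put_along_axis(gv, idx[..., None], g[..., None], axis=-1)
        gv = gv.reshape(n, c, h // size, w // size, size, size)
        gv = gv.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(gv)

    return _node(out, (x,), backward)


def avgpool2d(x: Tensor, size: int) -> Tensor:
    """Average pooling with window == stride == size (integral geometry)."""
    n, c, h, w = x.shape
    if h % size or w % size:
        raise ValueError(f"avgpool2d: spatial dims {(h, w)} not divisible by {size}")
    v = x.data.reshape(n, c, h // size, size, w // size, size)
    out = v.mean(axis=(3, 5))
    inv = 1.0 / (size * size)

    def backward(g):
        gx = np.broadcast_to((g * inv)[:, :, :, None, :, None],
                             (n, c, h // size, size, w // size, size))
        x._accum(gx.reshape(n, c, h, w).astype(x.dtype, copy=False))

    return _node(out, (x,), backward)


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    n, c, h, w = x.shape
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        gv = g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5))
        x._accum(gv)

    return _node(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype):
    """Dense 1-D bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        t = src - lo
        m[o, lo] += 1.0 - t
        m[o, hi] += t
    return m


def upsample_bilinear(x: Tensor, out_hw) -> Tensor:
    n, c, h, w = x.shape
    oh, ow = out_hw
    r = _interp_matrix(oh, h, x.data.dtype)
    cm = _interp_matrix(ow, w, x.data.dtype)
    out = np.einsum("oh,nchw,pw->ncop", r, x.data, cm, optimize=True)

    def backward(g):
        gx = np.einsum("oh,ncop,pw->nchw", r, g, cm, optimize=True)
        x._accum(gx)

    return _node(out, (x,), backward)


def _pool_matrix(n_out: int, n_in: int, dtype):
    """Row-stochastic averaging matrix for adaptive mean pooling."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    for o in range(n_out):
        start = (o * n_in) // n_out
        end = -(-((o + 1) * n_in) // n_out)  # ceil
        m[o, start:end] = 1.0 / (end - start)
    return m


def _nearest_matrix(n_out: int, n_in: int, dtype):
    m = np.zeros((n_out, n_in), dtype=dtype)
    for o in range(n_out):
        src = min(int(o * n_in / n_out), n_in - 1)
        m[o, src] = 1.0
    return m


def _sep_linear(x: Tensor, r: np.ndarray, c: np.ndarray) -> Tensor:
    """Separable linear spatial map out = R . x . C^T on NCHW tensors."""
    out = np.einsum("oh,nchw,pw->ncop", r, x.data, c, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", r, g, c, optimize=True))

    return _node(out, (x,), backward)


def adaptive_avgpool2d(x: Tensor, out_hw) -> Tensor:
    oh, ow = out_hw
    if x.shape[2] < oh or x.shape[3] < ow:
        raise ValueError(
            f"adaptive_avgpool2d: input {x.shape[2:]} smaller than grid {(oh, ow)}")
    return _sep_linear(x, _pool_matrix(oh, x.shape[2], x.data.dtype),
                       _pool_matrix(ow, x.shape[3], x.data.dtype))


def resize_nearest(x: Tensor, out_hw) -> Tensor:
    oh, ow = out_hw
    return _sep_linear(x, _nearest_matrix(oh, x.shape[2], x.data.dtype),
                       _nearest_matrix(ow, x.shape[3], x.data.dtype))


# -- loss ---------------------------------------------------------------------

def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pixel-wise cross-entropy; logits (N, C, H, W), labels (N, H, W) ints."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - lse
    n, c, h, w = z.shape
    picked = np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]
    loss = -picked.mean()
    count = picked.size

    def backward(g):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        logits._accum(g * (p - onehot) / count)

    return _node(np.asarray(loss, dtype=z.dtype), (logits,), backward)
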