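"""Neural-network operations on :class:`~hyperseg.nn.tensor.Tensor`.

Convolutions use im2col/col2im; images are NCHW.  The scalar helpers at the
bottom (``tanh``, ``arctanh``, ...) dispatch on input type so the Poincare-ball
geometry can be written once and run on plain numpy arrays (inference, tests)
or on tensors inside the autodiff graph (training).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

from .tensor import Tensor, as_tensor

__all__ = [
    "conv2d", "conv_transpose2d", "dilate2d", "bilinear_resize",
    "layer_norm", "softmax", "log_softmax", "gelu", "relu",
    "concat", "stack",
    "tanh", "arctanh", "arcsinh", "sqrt", "exp", "log", "clip", "where",
    "sum_last", "norm_last", "is_tensor",
]


# --------------------------------------------------------------------- conv
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, oh, ow),
        (s0, s1, s2, s3, s2 * stride, s3 * stride))
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, xshape, kh, kw, stride, pad):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    oh, ow = dcols.shape[-2:]
    dx = np.zeros((n, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                dcols[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution; ``x`` NCHW, ``w`` (Cout, Cin/groups, kh, kw)."""
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    n, cin, h, wid = xd.shape
    cout, cing, kh, kw = wd.shape
    if cin != cing * groups or cout % groups:
        raise ValueError("channel/group mismatch in conv2d")
    cols, oh, ow = _im2col(xd, kh, kw, stride, padding)
    colsg = cols.reshape(n, groups, cing * kh * kw, oh * ow)
    wg = wd.reshape(groups, cout // groups, cing * kh * kw)
    out = np.einsum("gok,ngkl->ngol", wg, colsg, optimize=True)
    out = out.reshape(n, cout, oh, ow)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, cout, 1, 1)
        parents.append(b)

    def backward(g):
        gg = g.reshape(n, groups, cout // groups, oh * ow)
        dw = np.einsum("ngol,ngkl->gok", gg, colsg, optimize=True)
        dcols = np.einsum("gok,ngol->ngkl", wg, gg, optimize=True)
        dcols = dcols.reshape(n, cin, kh, kw, oh, ow)
        dx = _col2im(dcols, xd.shape, kh, kw, stride, padding)
        grads = [dx, dw.reshape(wd.shape)]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return grads

    return Tensor._make(out, parents, backward)


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between spatial elements (NCHW)."""
    x = as_tensor(x)
    if stride == 1:
        return x
    n, c, h, w = x.data.shape
    out = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1))
    out[:, :, ::stride, ::stride] = x.data
    return Tensor._make(out, (x,), lambda g: (g[:, :, ::stride, ::stride],))


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Transposed convolution; ``w`` (Cin, Cout, kh, kw), torch layout."""
    w = as_tensor(w)
    kh = w.shape[2]
    xd = dilate2d(x, stride)
    wf = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    return conv2d(xd, wf, b, stride=1, padding=kh - 1 - padding)


def bilinear_resize(x, out_h: int, out_w: int):
    """Bilinear resize of an NCHW map (half-pixel centers, no corner align).

    Polymorphic: accepts a Tensor (differentiable) or an ndarray.
    """
    h, w = (x.data if isinstance(x, Tensor) else x).shape[-2:]

    def grid(out_n, n):
        s = np.clip((np.arange(out_n) + 0.5) * n / out_n - 0.5, 0, n - 1)
        i0 = np.floor(s).astype(int)
        i1 = np.minimum(i0 + 1, n - 1)
        return i0, i1, s - i0

    y0, y1, fy = grid(out_h, h)
    x0, x1, fx = grid(out_w, w)
    Y0, X0 = np.meshgrid(y0, x0, indexing="ij")
    Y1, X1 = np.meshgrid(y1, x1, indexing="ij")
    FY = fy[:, None]
    FX = fx[None, :]
    sl = (slice(None), slice(None))
    tl = x[sl + (Y0, X0)]
    tr = x[sl + (Y0, X1)]
    bl = x[sl + (Y1, X0)]
    br = x[sl + (Y1, X1)]
    top = tl * (1 - FX) + tr * FX
    bot = bl * (1 - FX) + br * FX
    return top * (1 - FY) + bot * FY


# ----------------------------------------------------------- normalization
def layer_norm(x: Tensor, weight: Tensor, bias: Tensor, eps: float = 1e-6):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xn = xc / (var + eps).sqrt()
    return xn * weight + bias


def softmax(x, axis=-1):
    if isinstance(x, Tensor):
        m = x.data.max(axis=axis, keepdims=True)
        e = (x - m).exp()
        return e / e.sum(axis=axis, keepdims=True)
    m = x.max(axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis=-1):
    m = x.data.max(axis=axis, keepdims=True)
    xs = x - m
    return xs - xs.exp().sum(axis=axis, keepdims=True).log()


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit."""
    x = as_tensor(x)
    a = x.data
    phi = 0.5 * (1.0 + _erf(a / np.sqrt(2.0)))
    out = a * phi
    dens = np.exp(-0.5 * a * a) / np.sqrt(2.0 * np.pi)
    return Tensor._make(out, (x,), lambda g: (g * (phi + a * dens),))


def relu(x):
    return x.relu() if isinstance(x, Tensor) else np.maximum(x, 0)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return [np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
                for i in range(len(datas))]

    return Tensor._make(out, tensors, backward)


def stack(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return [np.take(g, i, axis=axis) for i in range(len(tensors))]

    return Tensor._make(out, tensors, backward)


# ----------------------------------------------- type-polymorphic helpers
def is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def tanh(x):
    return x.tanh() if isinstance(x, Tensor) else np.tanh(x)


def arctanh(x):
    return x.arctanh() if isinstance(x, Tensor) else np.arctanh(x)


def arcsinh(x):
    return x.arcsinh() if isinstance(x, Tensor) else np.arcsinh(x)


def sqrt(x):
    return x.sqrt() if isinstance(x, Tensor) else np.sqrt(x)


def exp(x):
    return x.exp() if isinstance(x, Tensor) else np.exp(x)


def log(x):
    return x.log() if isinstance(x, Tensor) else np.log(x)


def clip(x, lo=None, hi=None):
    return x.clip(lo, hi) if isinstance(x, Tensor) else np.clip(x, lo, hi)


def where(cond, a, b):
    """Select elementwise; ``cond`` is a plain boolean array."""
    cond = np.asarray(cond)
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a, b = as_tensor(a), as_tensor(b)
        out = np.where(cond, np.broadcast_to(a.data, np.broadcast_shapes(
            cond.shape, a.data.shape, b.data.shape)),
            np.broadcast_to(b.data, np.broadcast_shapes(
                cond.shape, a.data.shape, b.data.shape)))
        return Tensor._make(out, (a, b),
                            lambda g: (g * cond, g * ~cond))
    return np.where(cond, a, b)


def sum_last(x, keepdims=True):
    return x.sum(axis=-1, keepdims=keepdims)


def norm_last(x, keepdims=True, eps: float = 0.0):
    """Euclidean norm along the last axis; optional floor for safe division."""
    sq = sum_last(x * x, keepdims=keepdims)
    n = sqrt(sq)
    if eps:
        n = clip(n, lo=eps)
    return n
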