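"""Reverse-mode automatic differentiation over numpy arrays.

This is the numerical core on which the complex-valued layers are built:
a :class:`Tensor` wraps an ndarray and records, for every operation, a
closure that propagates gradients to its parents.  Real and imaginary
parts of complex activations are represented as *independent real*
tensors, so a complex layer is simply a composition of the real ops
defined here and its gradients are the Wirtinger derivatives with
respect to the real/imaginary parameter pairs.

Convolutions are cross-correlations (deep-learning convention).  For
stride-1 kernels that are one-dimensional along an axis (the only wide
kernels used by the spectral and separable blocks) the forward and both
backward passes run through batched real FFTs; everything else uses a
direct sliding-window contraction.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as _sfft

__all__ = [
    "Tensor",
    "astensor",
    "no_grad",
    "add", "sub", "mul", "div", "neg",
    "exp", "log", "sqrt", "square", "maximum_const",
    "relu", "matmul", "reshape", "tsum", "tmean",
    "conv2d", "avgpool2d", "softmax",
    "Adam",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        # grads are never mutated in place, so sharing references is safe
        self.grad = g if self.grad is None else self.grad + g

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def _is_const(x) -> bool:
    """Python/numpy scalars and plain arrays act as graph constants; keeping
    them raw avoids wrapping scalars as float64 0-d arrays (which would
    silently upcast float32 activations)."""
    return not isinstance(x, Tensor)


def add(a, b):
    if _is_const(b):
        a = astensor(a)
        c = b

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))

        return _node(a.data + c, (a,), backward)
    if _is_const(a):
        return add(b, a)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def sub(a, b):
    if _is_const(b):
        a = astensor(a)
        c = b

        def backward(g):
            a._accumulate(_unbroadcast(g, a.data.shape))

        return _node(a.data - c, (a,), backward)
    if _is_const(a):
        c = a
        b_ = b

        def backward(g):
            b_._accumulate(_unbroadcast(-g, b_.data.shape))

        return _node(c - b_.data, (b_,), backward)
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b):
    if _is_const(b):
        a = astensor(a)
        c = b

        def backward(g):
            a._accumulate(_unbroadcast(g * c, a.data.shape))

        return _node(a.data * c, (a,), backward)
    if _is_const(a):
        return mul(b, a)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def div(a, b):
    if _is_const(b):
        inv = 1.0 / float(b) if np.isscalar(b) else 1.0 / np.asarray(b)
        return mul(a, inv)
    if _is_const(a):
        c = a
        b_ = b
        out_data = c / b_.data

        def backward(g):
            b_._accumulate(_unbroadcast(-g * out_data / b_.data, b_.data.shape))

        return _node(out_data, (b_,), backward)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _node(out_data, (a, b), backward)


def neg(a):
    a = astensor(a)

    def backward(g):
        a._accumulate(-g)

    return _node(-a.data, (a,), backward)


def exp(a):
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _node(out_data, (a,), backward)


def log(a):
    a = astensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _node(np.log(a.data), (a,), backward)


def sqrt(a):
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        # subgradient 0 at the origin keeps modulus training finite
        safe = np.where(out_data > 0, out_data, 1.0)
        a._accumulate(np.where(out_data > 0, g / (2.0 * safe), 0.0))

    return _node(out_data, (a,), backward)


def square(a):
    a = astensor(a)

    def backward(g):
        a._accumulate(g * (2.0 * a.data))

    return _node(a.data * a.data, (a,), backward)


def maximum_const(a, c: float):
    """Elementwise max(a, c); gradient flows only where a > c."""
    a = astensor(a)
    mask = a.data > c

    def backward(g):
        a._accumulate(g * mask)

    return _node(np.maximum(a.data, c), (a,), backward)


def relu(a):
    a = astensor(a)
    mask = a.data > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.data * mask, (a,), backward)


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        gg = g
        if not keepdims and axis is not None:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            axes = tuple(ax % a.data.ndim for ax in axes)
            gg = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(gg, a.data.shape).astype(a.data.dtype, copy=False))

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = astensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax % a.data.ndim] for ax in ((axis,) if np.isscalar(axis) else axis)]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = astensor(a)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return _node(a.data.reshape(shape), (a,), backward)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return _node(out_data, (a, b), backward)


def softmax(a, axis=-1):
    """Numerically stable softmax built from primitive ops."""
    a = astensor(a)
    shift = a.data.max(axis=axis, keepdims=True)  # constant w.r.t. the graph
    e = exp(sub(a, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

_FFT_MIN_KERNEL = 8


def conv2d(x, w, stride=(1, 1), padding=(0, 0), groups: int = 1):
    """Batched 2-D cross-correlation with channel groups.

    x: (B, Cin, H, W); w: (Cout, Cin//groups, kH, kW) -> (B, Cout, Ho, Wo).
    """
    x, w = astensor(x), astensor(w)
    B, Cin, H, W = x.data.shape
    Cout, Cing, kH, kW = w.data.shape
    if Cin % groups or Cout % groups:
        raise ValueError(f"groups={groups} must divide in_channels={Cin} and out_channels={Cout}")
    if Cing != Cin // groups:
        raise ValueError(f"kernel expects {Cing} channels/group, input provides {Cin // groups}")
    ph, pw = padding
    sh, sw = stride
    Hp, Wp = H + 2 * ph, W + 2 * pw
    if kH > Hp or kW > Wp:
        raise ValueError(f"kernel ({kH},{kW}) larger than padded input ({Hp},{Wp})")

    # FFT pays off for long kernels along the (contiguous) width axis; height
    # kernels contract to a small matmul and stay on the direct path
    use_fft = (sh, sw) == (1, 1) and kH == 1 and kW >= _FFT_MIN_KERNEL
    if use_fft:
        return _conv2d_fft(x, w, (ph, pw), groups)
    return _conv2d_direct(x, w, (sh, sw), (ph, pw), groups)


def _pad_hw(arr, ph, pw):
    if ph == 0 and pw == 0:
        return arr
    return np.pad(arr, ((0, 0), (0, 0), (ph, ph), (pw, pw)))


def _conv2d_direct(x: Tensor, w: Tensor, stride, padding, groups):
    sh, sw = stride
    ph, pw = padding
    B, Cin, H, W = x.data.shape
    Cout, Cing, kH, kW = w.data.shape
    g, Cog = groups, Cout // groups
    xp = _pad_hw(x.data, ph, pw)
    win = sliding_window_view(xp, (kH, kW), axis=(2, 3))[:, :, ::sh, ::sw]
    Ho, Wo = win.shape[2], win.shape[3]
    win_g = win.reshape(B, g, Cing, Ho, Wo, kH, kW)
    w_g = w.data.reshape(g, Cog, Cing, kH, kW)
    y = np.einsum("bgihwkl,goikl->bgohw", win_g, w_g, optimize=True)
    out_data = y.reshape(B, Cout, Ho, Wo)

    def backward(gy):
        gy_g = gy.reshape(B, g, Cog, Ho, Wo)
        if w.requires_grad or w._parents:
            gw = np.einsum("bgihwkl,bgohw->goikl", win_g, gy_g, optimize=True)
            w._accumulate(gw.reshape(Cout, Cing, kH, kW))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            gxp_g = gxp.reshape(B, g, Cing, xp.shape[2], xp.shape[3])
            if B * Cin * Ho * Wo * kH * kW <= 200_000_000:
                # one contraction, then cheap strided scatter-adds per tap
                gwin = np.einsum("bgohw,goikl->bgihwkl", gy_g, w_g, optimize=True)
                for i in range(kH):
                    for j in range(kW):
                        gxp_g[:, :, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += \
                            gwin[:, :, :, :, :, i, j]
            else:
                for i in range(kH):
                    for j in range(kW):
                        contrib = np.einsum("bgohw,goi->bgihw", gy_g,
                                            w_g[:, :, :, i, j], optimize=True)
                        gxp_g[:, :, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += contrib
            gx = gxp[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(gx)

    return _node(out_data, (x, w), backward)


def _conv2d_fft(x: Tensor, w: Tensor, padding, groups):
    """Stride-1 conv with a 1-D kernel along H or W, via real FFTs."""
    ph, pw = padding
    kH, kW = w.data.shape[2], w.data.shape[3]
    along_h = kH > 1
    B, Cin, H, W = x.data.shape
    Cout, Cing, _, _ = w.data.shape
    g, Cog = groups, Cout // groups

    xp = _pad_hw(x.data, ph, pw)
    if along_h:
        xp_w = np.swapaxes(xp, 2, 3)  # kernel axis last
        k = kH
    else:
        xp_w = xp
        k = kW
    *_, Ax, L0 = xp_w.shape
    w1 = w.data.reshape(Cout, Cing, k)
    L = _sfft.next_fast_len(L0)
    Wo = L0 - k + 1

    Xf = _sfft.rfft(xp_w, L, axis=-1)                # (B, Cin, Ax, F)
    Kf = _sfft.rfft(w1[:, :, ::-1], L, axis=-1)      # (Cout, Cing, F)
    Xf_g = Xf.reshape(B, g, Cing, Ax, Xf.shape[-1])
    Kf_g = Kf.reshape(g, Cog, Cing, Kf.shape[-1])
    Yf = np.einsum("bgiaf,goif->bgoaf", Xf_g, Kf_g, optimize=True)
    y = _sfft.irfft(Yf.reshape(B, Cout, Ax, -1), L, axis=-1)[..., k - 1:L0]
    out_data = np.swapaxes(y, 2, 3) if along_h else y
    out_data = np.ascontiguousarray(out_data)

    def backward(gy):
        gy_w = np.swapaxes(gy, 2, 3) if along_h else gy  # (B, Cout, Ax, Wo)
        GYf = _sfft.rfft(gy_w, L, axis=-1)
        GYf_g = GYf.reshape(B, g, Cog, Ax, GYf.shape[-1])
        if w.requires_grad or w._parents:
            Cf = np.einsum("bgiaf,bgoaf->goif", Xf_g, np.conj(GYf_g), optimize=True)
            corr = _sfft.irfft(Cf.reshape(Cout, Cing, -1), L, axis=-1)[..., :k]
            w._accumulate(corr.reshape(w.data.shape))
        if x.requires_grad or x._parents:
            Kf2 = _sfft.rfft(w1, L, axis=-1).reshape(g, Cog, Cing, -1)
            GXf = np.einsum("bgoaf,goif->bgiaf", GYf_g, Kf2, optimize=True)
            gxp_w = _sfft.irfft(GXf.reshape(B, Cin, Ax, -1), L, axis=-1)[..., :L0]
            gxp = np.swapaxes(gxp_w, 2, 3) if along_h else gxp_w
            gx = gxp[:, :, ph:ph + H, pw:pw + W]
            x._accumulate(np.ascontiguousarray(gx))

    return _node(out_data, (x, w), backward)


def avgpool2d(x, window, stride=None):
    """Average pooling with floor semantics: trailing partial windows dropped."""
    x = astensor(x)
    wh, ww = window
    sh, sw = (wh, ww) if stride is None else stride
    B, C, H, W = x.data.shape
    if wh > H or ww > W:
        raise ValueError(f"pool window ({wh},{ww}) larger than input ({H},{W})")
    win = sliding_window_view(x.data, (wh, ww), axis=(2, 3))[:, :, ::sh, ::sw]
    Ho, Wo = win.shape[2], win.shape[3]
    out_data = win.mean(axis=(-2, -1))
    n = float(wh * ww)

    def backward(g):
        gx = np.zeros_like(x.data)
        gs = g / n
        for i in range(wh):
            for j in range(ww):
                gx[:, :, i:i + Ho * sh:sh, j:j + Wo * sw:sw] += gs
        x._accumulate(gx)

    return _node(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# fused ops for the complex layers
# ---------------------------------------------------------------------------

def batchnorm(x: Tensor, axes=(0, 2, 3), eps: float = 1e-5):
    """Standardize over `axes` with an analytic (fused) backward pass.

    Returns (xhat node, mean, biased variance); the statistics are plain
    per-channel arrays for running-average bookkeeping.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv

    def backward(g):
        gm = g.mean(axis=axes, keepdims=True)
        gxm = (g * xhat).mean(axis=axes, keepdims=True)
        x._accumulate(inv * (g - gm - xhat * gxm))

    node = _node(xhat, (x,), backward)
    return node, mu.squeeze(), var.squeeze()


def complex_affine(zr, zi, gamma_r, gamma_i, beta_r, beta_i):
    """Per-channel complex scale-and-shift of a (B, C, H, W) pair:
    out = gamma * z + beta with gamma, beta complex vectors of length C."""
    shape = (1, -1, 1, 1)
    grd = gamma_r.data.reshape(shape)
    gid = gamma_i.data.reshape(shape)
    out_r_data = grd * zr.data - gid * zi.data + beta_r.data.reshape(shape)
    out_i_data = grd * zi.data + gid * zr.data + beta_i.data.reshape(shape)
    red = (0, 2, 3)

    def backward_r(g):
        if zr.requires_grad or zr._parents:
            zr._accumulate(g * grd)
        if zi.requires_grad or zi._parents:
            zi._accumulate(-(g * gid))
        if gamma_r.requires_grad:
            gamma_r._accumulate((g * zr.data).sum(axis=red))
        if gamma_i.requires_grad:
            gamma_i._accumulate(-(g * zi.data).sum(axis=red))
        if beta_r.requires_grad:
            beta_r._accumulate(g.sum(axis=red))

    def backward_i(g):
        if zr.requires_grad or zr._parents:
            zr._accumulate(g * gid)
        if zi.requires_grad or zi._parents:
            zi._accumulate(g * grd)
        if gamma_r.requires_grad:
            gamma_r._accumulate((g * zi.data).sum(axis=red))
        if gamma_i.requires_grad:
            gamma_i._accumulate((g * zr.data).sum(axis=red))
        if beta_i.requires_grad:
            beta_i._accumulate(g.sum(axis=red))

    out_r = _node(out_r_data, (zr, zi, gamma_r, gamma_i, beta_r), backward_r)
    out_i = _node(out_i_data, (zr, zi, gamma_r, gamma_i, beta_i), backward_i)
    return out_r, out_i


def cconv2d_fft_pair(xr, xi, wr, wi, padding=(0, 0), groups: int = 1):
    """Complex convolution via a single complex FFT per pass.

    The (real, imag) tensor pairs are combined into complex arrays, so the
    four real cross-correlations of the complex product collapse into one
    spectral multiplication.  Stride 1, kernel one-dimensional along H or W.
    Returns the (real, imag) output pair.
    """
    B, Cin, H, W = xr.data.shape
    Cout, Cing, kH, kW = wr.data.shape
    ph, pw = padding
    along_h = kH > 1
    g, Cog = groups, Cout // groups

    z = xr.data + 1j * xi.data
    zp = _pad_hw(z, ph, pw)
    if along_h:
        zp = np.swapaxes(zp, 2, 3)
        k = kH
    else:
        k = kW
    Ax, L0 = zp.shape[-2], zp.shape[-1]
    L = _sfft.next_fast_len(L0)
    Wo = L0 - k + 1
    wc = (wr.data + 1j * wi.data).reshape(Cout, Cing, k)

    Zf = _sfft.fft(zp, L, axis=-1)
    Kf = _sfft.fft(wc[:, :, ::-1], L, axis=-1)
    Zf_g = Zf.reshape(B, g, Cing, Ax, L)
    Kf_g = Kf.reshape(g, Cog, Cing, L)
    if Cing == 1:
        Yf = Zf_g[:, :, 0][:, :, None] * Kf_g[:, :, 0][None, :, :, None]
    else:
        Yf = np.einsum("bgiaf,goif->bgoaf", Zf_g, Kf_g, optimize=True)
    y = _sfft.ifft(Yf.reshape(B, Cout, Ax, L), axis=-1)[..., k - 1:L0]
    if along_h:
        y = np.swapaxes(y, 2, 3)
    out_r_data = np.ascontiguousarray(y.real)
    out_i_data = np.ascontiguousarray(y.imag)

    need_x = any(t.requires_grad or t._parents for t in (xr, xi))
    need_w = any(t.requires_grad or t._parents for t in (wr, wi))

    def make_backward(phase):
        def backward(gout):
            gor = np.swapaxes(gout, 2, 3) if along_h else gout
            # gout is real: half-spectrum rfft + hermitian extension is cheaper
            GFh = _sfft.rfft(gor, L, axis=-1)
            GF = np.empty(gor.shape[:-1] + (L,), dtype=GFh.dtype)
            half = L // 2 + 1
            GF[..., :half] = GFh
            tail = L - half
            if tail:
                GF[..., half:] = np.conj(GFh[..., 1:1 + tail][..., ::-1])
            if phase != 1.0:
                GF = GF * phase
            GF_g = GF.reshape(B, g, Cog, Ax, L)
            if need_w:
                # gw[l] = conj( sum_t zp[t+l] * conj(gc[t]) ), circular corr via FFT
                if Cing == 1:
                    S = np.einsum("bgaf,bgoaf->gof", Zf_g[:, :, 0], np.conj(GF_g),
                                  optimize=True)[:, :, None]
                else:
                    S = np.einsum("bgiaf,bgoaf->goif", Zf_g, np.conj(GF_g),
                                  optimize=True)
                gw_c = np.conj(_sfft.ifft(S, axis=-1)[..., :k]).reshape(Cout, Cing, k)
                gw_c = gw_c.reshape(wr.data.shape)
                if wr.requires_grad or wr._parents:
                    wr._accumulate(np.ascontiguousarray(gw_c.real))
                if wi.requires_grad or wi._parents:
                    wi._accumulate(np.ascontiguousarray(gw_c.imag))
            if need_x:
                FKc = _sfft.fft(np.conj(wc), L, axis=-1).reshape(g, Cog, Cing, L)
                if Cing == 1:
                    GXf = np.einsum("bgoaf,gof->bgaf", GF_g, FKc[:, :, 0],
                                    optimize=True)[:, :, None]
                else:
                    GXf = np.einsum("bgoaf,goif->bgiaf", GF_g, FKc, optimize=True)
                gz = _sfft.ifft(GXf.reshape(B, Cin, Ax, L), axis=-1)[..., :L0]
                if along_h:
                    gz = np.swapaxes(gz, 2, 3)
                gz = gz[:, :, ph:ph + H, pw:pw + W]
                if xr.requires_grad or xr._parents:
                    xr._accumulate(np.ascontiguousarray(gz.real))
                if xi.requires_grad or xi._parents:
                    xi._accumulate(np.ascontiguousarray(gz.imag))

        return backward

    parents = (xr, xi, wr, wi)
    out_r = _node(out_r_data, parents, make_backward(1.0))
    out_i = _node(out_i_data, parents, make_backward(1.0j))
    return out_r, out_i


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the conventional defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, lr=0.001, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
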