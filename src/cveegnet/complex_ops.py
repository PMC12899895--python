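"""Complex-valued layer primitives.

A complex activation is a pair of real tensors (real, imag).  All layer
algebra follows the complex product: for input H = Hr + iHi and kernel
W = Wr + iWi,

    H * W = (Hr*Wr - Hi*Wi) + i(Hr*Wi + Hi*Wr)

where ``*`` is (real) convolution or matrix product.  Pooling and the
split ReLU act on the two parts independently; the modulus readout maps
a complex tensor to its elementwise magnitude sqrt(Re^2 + Im^2).

Batch normalization standardizes the real and imaginary parts by their
own per-channel batch statistics and then applies a single complex
affine transform (complex gamma, complex beta), the simplest reading of
a joint real/imaginary affine that keeps the parameter budget of the
published architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor, astensor
from .errors import ConfigurationError, DegenerateBatchError, DimensionError

__all__ = [
    "ComplexTensor", "ComplexKernel", "ComplexLinearParams", "ComplexBNParams",
    "cconv2d", "cavgpool", "crelu", "clinear", "cbatchnorm", "modulus",
    "CConv2d", "CLinear", "CBatchNorm2d", "CAvgPool2d", "CReLU",
]


class ComplexTensor:
    """A complex array carried as two real tensors of identical shape."""

    __slots__ = ("real", "imag")

    def __init__(self, real, imag):
        self.real = astensor(real)
        self.imag = astensor(imag)
        if self.real.shape != self.imag.shape:
            raise DimensionError(
                f"real/imag shapes differ: {self.real.shape} vs {self.imag.shape}"
            )

    @classmethod
    def from_complex(cls, z) -> "ComplexTensor":
        z = np.asarray(z)
        return cls(np.ascontiguousarray(z.real), np.ascontiguousarray(z.imag))

    @property
    def shape(self):
        return self.real.shape

    def numpy(self) -> np.ndarray:
        return self.real.data + 1j * self.imag.data

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.real.data, self.imag.data)

    def reshape(self, shape) -> "ComplexTensor":
        return ComplexTensor(ag.reshape(self.real, shape), ag.reshape(self.imag, shape))

    def __repr__(self):
        return f"ComplexTensor(shape={self.shape})"


def _init_pair(rng: np.random.Generator, shape, fan_in: int, dtype):
    """Zero-mean init with per-part variance 1/(2*fan_in).

    Halving the real-valued fan-in variance makes the variance of the
    complex product match the real convention.
    """
    std = np.sqrt(1.0 / (2.0 * fan_in))
    re = rng.normal(0.0, std, size=shape).astype(dtype)
    im = rng.normal(0.0, std, size=shape).astype(dtype)
    return Tensor(re, requires_grad=True), Tensor(im, requires_grad=True)


@dataclass
class ComplexKernel:
    """Complex convolution kernel (out_ch, in_ch/groups, kH, kW) with optional bias."""

    w_real: Tensor
    w_imag: Tensor
    b_real: Optional[Tensor] = None
    b_imag: Optional[Tensor] = None

    def __post_init__(self):
        self.w_real = astensor(self.w_real)
        self.w_imag = astensor(self.w_imag)
        if self.w_real.shape != self.w_imag.shape:
            raise DimensionError("kernel real/imag shapes differ")
        if self.b_real is not None:
            self.b_real = astensor(self.b_real)
            self.b_imag = astensor(self.b_imag)

    @classmethod
    def initialize(cls, rng, out_ch, in_ch, kh, kw, groups=1, bias=True,
                   dtype=np.float64) -> "ComplexKernel":
        if in_ch % groups or out_ch % groups:
            raise ConfigurationError(
                f"groups={groups} must divide in_channels={in_ch} and out_channels={out_ch}"
            )
        cing = in_ch // groups
        wr, wi = _init_pair(rng, (out_ch, cing, kh, kw), cing * kh * kw, dtype)
        br = bi = None
        if bias:
            br = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
            bi = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)
        return cls(wr, wi, br, bi)


@dataclass
class ComplexLinearParams:
    """Complex dense map (out_dim, in_dim) with complex bias."""

    w_real: Tensor
    w_imag: Tensor
    b_real: Optional[Tensor] = None
    b_imag: Optional[Tensor] = None

    def __post_init__(self):
        self.w_real = astensor(self.w_real)
        self.w_imag = astensor(self.w_imag)
        if self.w_real.shape != self.w_imag.shape:
            raise DimensionError("weight real/imag shapes differ")
        if self.b_real is not None:
            self.b_real = astensor(self.b_real)
            self.b_imag = astensor(self.b_imag)

    @classmethod
    def initialize(cls, rng, out_dim, in_dim, bias=True, dtype=np.float64):
        wr, wi = _init_pair(rng, (out_dim, in_dim), in_dim, dtype)
        br = bi = None
        if bias:
            br = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True)
            bi = Tensor(np.zeros(out_dim, dtype=dtype), requires_grad=True)
        return cls(wr, wi, br, bi)


@dataclass
class ComplexBNParams:
    """Split-standardization batch norm with a complex per-channel affine."""

    gamma_real: Tensor
    gamma_imag: Tensor
    beta_real: Tensor
    beta_imag: Tensor
    running_mean_real: np.ndarray = field(repr=False, default=None)
    running_mean_imag: np.ndarray = field(repr=False, default=None)
    running_var_real: np.ndarray = field(repr=False, default=None)
    running_var_imag: np.ndarray = field(repr=False, default=None)
    eps: float = 1e-5
    momentum: float = 0.1

    @classmethod
    def initialize(cls, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                   dtype=np.float64):
        one = np.ones(channels, dtype=dtype)
        zero = np.zeros(channels, dtype=dtype)
        return cls(
            gamma_real=Tensor(one.copy(), requires_grad=True),
            gamma_imag=Tensor(zero.copy(), requires_grad=True),
            beta_real=Tensor(zero.copy(), requires_grad=True),
            beta_imag=Tensor(zero.copy(), requires_grad=True),
            running_mean_real=zero.copy(), running_mean_imag=zero.copy(),
            running_var_real=one.copy(), running_var_imag=one.copy(),
            eps=eps, momentum=momentum,
        )


# ---------------------------------------------------------------------------
# functional operations
# ---------------------------------------------------------------------------

def cconv2d(x: ComplexTensor, kernel: ComplexKernel, stride=(1, 1), padding=(0, 0),
            groups: int = 1) -> ComplexTensor:
    """Complex 2-D convolution (cross-correlation) with channel groups."""
    if x.real.ndim != 4:
        raise DimensionError(f"expected (B, Cin, H, W) input, got shape {x.shape}")
    cin = x.shape[1]
    cout, cing = kernel.w_real.shape[0], kernel.w_real.shape[1]
    if cin % groups or cout % groups:
        raise ConfigurationError(
            f"groups={groups} must divide in_channels={cin} and out_channels={cout}"
        )
    if cing != cin // groups:
        raise DimensionError(
            f"kernel expects {cing} channels per group, input provides {cin // groups}"
        )
    kh, kw = kernel.w_real.shape[2], kernel.w_real.shape[3]
    ph, pw = padding
    if kh > x.shape[2] + 2 * ph or kw > x.shape[3] + 2 * pw:
        raise DimensionError(
            f"kernel ({kh},{kw}) larger than padded input "
            f"({x.shape[2] + 2 * ph},{x.shape[3] + 2 * pw})"
        )
    fused = tuple(stride) == (1, 1) and kh == 1 and kw >= ag._FFT_MIN_KERNEL
    try:
        if fused:
            out_r, out_i = ag.cconv2d_fft_pair(
                x.real, x.imag, kernel.w_real, kernel.w_imag, padding, groups
            )
        else:
            rr = ag.conv2d(x.real, kernel.w_real, stride, padding, groups)
            ii = ag.conv2d(x.imag, kernel.w_imag, stride, padding, groups)
            ri = ag.conv2d(x.real, kernel.w_imag, stride, padding, groups)
            ir = ag.conv2d(x.imag, kernel.w_real, stride, padding, groups)
            out_r = ag.sub(rr, ii)
            out_i = ag.add(ri, ir)
    except ValueError as e:
        raise DimensionError(str(e)) from e
    if kernel.b_real is not None:
        shape = (1, cout, 1, 1)
        out_r = ag.add(out_r, ag.reshape(kernel.b_real, shape))
        out_i = ag.add(out_i, ag.reshape(kernel.b_imag, shape))
    return ComplexTensor(out_r, out_i)


def cavgpool(x: ComplexTensor, window, stride=None) -> ComplexTensor:
    """Complex average pooling: the mean is taken per part over each window."""
    try:
        return ComplexTensor(
            ag.avgpool2d(x.real, window, stride),
            ag.avgpool2d(x.imag, window, stride),
        )
    except ValueError as e:
        raise DimensionError(str(e)) from e


def crelu(x: ComplexTensor) -> ComplexTensor:
    """Split ReLU: rectify real and imaginary parts independently."""
    return ComplexTensor(ag.relu(x.real), ag.relu(x.imag))


def clinear(x: ComplexTensor, params: ComplexLinearParams) -> ComplexTensor:
    """Complex dense layer: Y = W H + b with W, H, b complex."""
    if x.real.ndim != 2:
        raise DimensionError(f"expected (B, in_dim) input, got shape {x.shape}")
    in_dim = x.shape[1]
    if params.w_real.shape[1] != in_dim:
        raise DimensionError(
            f"weight expects in_dim={params.w_real.shape[1]}, input has {in_dim}"
        )
    rr = ag.matmul(x.real, _transpose(params.w_real))
    ii = ag.matmul(x.imag, _transpose(params.w_imag))
    ri = ag.matmul(x.imag, _transpose(params.w_real))
    ir = ag.matmul(x.real, _transpose(params.w_imag))
    out_r = ag.sub(rr, ii)
    out_i = ag.add(ri, ir)
    if params.b_real is not None:
        out_r = ag.add(out_r, params.b_real)
        out_i = ag.add(out_i, params.b_imag)
    return ComplexTensor(out_r, out_i)


def _transpose(t: Tensor) -> Tensor:
    out_data = t.data.T

    def backward(g):
        t._accumulate(g.T)

    return ag._node(out_data, (t,), backward)


def cbatchnorm(x: ComplexTensor, params: ComplexBNParams, training: bool) -> ComplexTensor:
    """Per-part standardization followed by a complex affine transform."""
    if x.real.ndim != 4:
        raise DimensionError(f"expected (B, C, H, W) input, got shape {x.shape}")
    ch = x.shape[1]
    if params.gamma_real.shape[0] != ch:
        raise DimensionError(f"norm has {params.gamma_real.shape[0]} channels, input {ch}")
    axes = (0, 2, 3)
    shape = (1, ch, 1, 1)

    def standardize(part: Tensor, rmean: np.ndarray, rvar: np.ndarray):
        if training:
            n = part.data.shape[0] * part.data.shape[2] * part.data.shape[3]
            z, mu, var = ag.batchnorm(part, axes=axes, eps=params.eps)
            # running statistics track the unbiased batch variance
            m = params.momentum
            rmean *= (1 - m)
            rmean += m * np.atleast_1d(mu)
            rvar *= (1 - m)
            rvar += m * np.atleast_1d(var) * (n / max(n - 1, 1))
            return z
        mu = rmean.reshape(shape)
        sd = np.sqrt(rvar.reshape(shape) + params.eps)
        return ag.div(ag.sub(part, mu), sd)

    if training and x.shape[0] < 2:
        raise DegenerateBatchError("batch normalization in training mode needs batch size >= 2")

    zr = standardize(x.real, params.running_mean_real, params.running_var_real)
    zi = standardize(x.imag, params.running_mean_imag, params.running_var_imag)
    out_r, out_i = ag.complex_affine(
        zr, zi, params.gamma_real, params.gamma_imag,
        params.beta_real, params.beta_imag,
    )
    return ComplexTensor(out_r, out_i)


def modulus(x: ComplexTensor) -> Tensor:
    """Elementwise magnitude sqrt(Re^2 + Im^2); invariant to global phase."""
    return ag.sqrt(ag.add(ag.square(x.real), ag.square(x.imag)))


# ---------------------------------------------------------------------------
# layer wrappers (stateful modules used to assemble networks)
# ---------------------------------------------------------------------------

class _Layer:
    def parameters(self):
        out = []
        for pair in self.parameter_pairs():
            out.extend(pair)
        return out

    def parameter_pairs(self):
        """List of (real, imag) trainable tensor pairs; one pair = one complex array."""
        return []


class CConv2d(_Layer):
    def __init__(self, rng, in_ch, out_ch, kernel_size, stride=(1, 1), padding=(0, 0),
                 groups=1, bias=True, dtype=np.float64):
        self.kernel = ComplexKernel.initialize(
            rng, out_ch, in_ch, kernel_size[0], kernel_size[1], groups, bias, dtype
        )
        self.stride, self.padding, self.groups = stride, padding, groups

    def __call__(self, x: ComplexTensor) -> ComplexTensor:
        return cconv2d(x, self.kernel, self.stride, self.padding, self.groups)

    def parameter_pairs(self):
        pairs = [(self.kernel.w_real, self.kernel.w_imag)]
        if self.kernel.b_real is not None:
            pairs.append((self.kernel.b_real, self.kernel.b_imag))
        return pairs


class CLinear(_Layer):
    def __init__(self, rng, in_dim, out_dim, bias=True, dtype=np.float64):
        self.params = ComplexLinearParams.initialize(rng, out_dim, in_dim, bias, dtype)

    def __call__(self, x: ComplexTensor) -> ComplexTensor:
        return clinear(x, self.params)

    def parameter_pairs(self):
        pairs = [(self.params.w_real, self.params.w_imag)]
        if self.params.b_real is not None:
            pairs.append((self.params.b_real, self.params.b_imag))
        return pairs


class CBatchNorm2d(_Layer):
    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float64):
        self.params = ComplexBNParams.initialize(channels, eps, momentum, dtype)
        self.training = True

    def __call__(self, x: ComplexTensor) -> ComplexTensor:
        return cbatchnorm(x, self.params, self.training)

    def parameter_pairs(self):
        p = self.params
        return [(p.gamma_real, p.gamma_imag), (p.beta_real, p.beta_imag)]


class CAvgPool2d(_Layer):
    def __init__(self, window, stride=None):
        self.window, self.stride = window, stride

    def __call__(self, x: ComplexTensor) -> ComplexTensor:
        return cavgpool(x, self.window, self.stride)


class CReLU(_Layer):
    def __call__(self, x: ComplexTensor) -> ComplexTensor:
        return crelu(x)
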