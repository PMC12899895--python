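"""Complex layer primitives: hand-worked examples, algebraic properties,
and agreement with brute-force complex-arithmetic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cveegnet import autograd as ag
from cveegnet.complex_ops import (
    CBatchNorm2d, ComplexBNParams, ComplexKernel, ComplexLinearParams,
    ComplexTensor, cavgpool, cbatchnorm, cconv2d, clinear, crelu, modulus,
)
from cveegnet.errors import ConfigurationError, DegenerateBatchError, DimensionError
from oracles import complex_conv2d_oracle, complex_linear_oracle

rng = np.random.default_rng(99)


def ct(z):
    z = np.asarray(z, dtype=complex)
    return ComplexTensor(z.real.copy(), z.imag.copy())


def kernel_of(z, bias=None):
    z = np.asarray(z, dtype=complex)
    if bias is None:
        return ComplexKernel(z.real.copy(), z.imag.copy())
    bias = np.asarray(bias, dtype=complex)
    return ComplexKernel(z.real.copy(), z.imag.copy(), bias.real.copy(), bias.imag.copy())


# ---------------------------------------------------------------------------
# cconv2d
# ---------------------------------------------------------------------------

def test_cconv2d_real_only_reduces_to_real_convolution():
    x = rng.normal(size=(2, 2, 4, 4))
    w = rng.normal(size=(3, 2, 2, 2))
    out = cconv2d(ct(x + 0j), kernel_of(w + 0j))
    ref = ag.conv2d(ag.Tensor(x), ag.Tensor(w)).data
    assert np.allclose(out.real.data, ref)
    assert np.allclose(out.imag.data, 0)


def test_cconv2d_multiplication_by_i_rotates_phase():
    z = rng.normal(size=(1, 1, 3, 3)) + 1j * rng.normal(size=(1, 1, 3, 3))
    w = np.array([[[[1j]]]])
    out = cconv2d(ct(z), kernel_of(w)).numpy()
    assert np.allclose(out, 1j * z)


def test_cconv2d_worked_example():
    # row [1+1i, 2-1i] * (1+1i) -> [0+2i, 3+1i]
    x = np.array([[[[1 + 1j, 2 - 1j]]]])
    w = np.array([[[[1 + 1j]]]])
    out = cconv2d(ct(x), kernel_of(w)).numpy()
    expected = complex_conv2d_oracle(x, w)
    assert np.allclose(expected.ravel(), [0 + 2j, 3 + 1j])
    assert np.allclose(out, expected)


def test_cconv2d_linearity_in_input():
    x = rng.normal(size=(1, 2, 4, 4)) + 1j * rng.normal(size=(1, 2, 4, 4))
    y = rng.normal(size=(1, 2, 4, 4)) + 1j * rng.normal(size=(1, 2, 4, 4))
    w = rng.normal(size=(3, 2, 2, 2)) + 1j * rng.normal(size=(3, 2, 2, 2))
    alpha, beta = 1.3 - 0.7j, -0.2 + 2.1j
    k = kernel_of(w)  # no bias
    lhs = cconv2d(ct(alpha * x + beta * y), k).numpy()
    rhs = alpha * cconv2d(ct(x), k).numpy() + beta * cconv2d(ct(y), k).numpy()
    assert np.allclose(lhs, rhs)


def test_cconv2d_group_and_shape_errors():
    x = ct(rng.normal(size=(1, 4, 3, 3)) + 0j)
    w = kernel_of(rng.normal(size=(4, 2, 2, 2)) + 0j)
    with pytest.raises(ConfigurationError):
        cconv2d(x, w, groups=3)
    with pytest.raises(DimensionError):
        cconv2d(x, w, groups=1)  # kernel expects 2 channels/group, input has 4
    with pytest.raises(DimensionError):
        cconv2d(ct(rng.normal(size=(1, 2, 1, 1)) + 0j),
                kernel_of(rng.normal(size=(2, 2, 3, 3)) + 0j))  # kernel > input


# ---------------------------------------------------------------------------
# cavgpool
# ---------------------------------------------------------------------------

def test_cavgpool_examples():
    const = np.full((1, 1, 4, 4), 2.5 - 1.5j)
    out = cavgpool(ct(const), (2, 2)).numpy()
    assert np.allclose(out, 2.5 - 1.5j)

    x = np.array([[[[1 + 2j, 3 + 4j]]]])
    assert np.allclose(cavgpool(ct(x), (1, 2)).numpy(), [[[[2 + 3j]]]])
    assert np.allclose(cavgpool(ct(x), (1, 1)).numpy(), x)


def test_cavgpool_commutes_with_complex_scaling():
    x = rng.normal(size=(2, 3, 4, 8)) + 1j * rng.normal(size=(2, 3, 4, 8))
    alpha = 0.3 - 1.9j
    lhs = cavgpool(ct(alpha * x), (2, 4)).numpy()
    rhs = alpha * cavgpool(ct(x), (2, 4)).numpy()
    assert np.allclose(lhs, rhs)


def test_cavgpool_window_too_large():
    with pytest.raises(DimensionError):
        cavgpool(ct(np.zeros((1, 1, 2, 2), dtype=complex)), (3, 3))


# ---------------------------------------------------------------------------
# crelu
# ---------------------------------------------------------------------------

def test_crelu_examples_and_idempotence():
    x = np.array([[-1 + 2j, -3 - 4j, 1 + 1j]])
    out = crelu(ComplexTensor(x.real.copy(), x.imag.copy())).numpy()
    assert np.allclose(out, [[0 + 2j, 0 + 0j, 1 + 1j]])


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_crelu_idempotent(seed):
    r = np.random.default_rng(seed)
    z = r.normal(size=(2, 5)) + 1j * r.normal(size=(2, 5))
    once = crelu(ct(z))
    twice = crelu(once)
    assert np.allclose(once.numpy(), twice.numpy())


# ---------------------------------------------------------------------------
# clinear
# ---------------------------------------------------------------------------

def test_clinear_identity_and_rotation():
    z = rng.normal(size=(3, 4)) + 1j * rng.normal(size=(3, 4))
    eye = ComplexLinearParams(np.eye(4), np.zeros((4, 4)))
    assert np.allclose(clinear(ct(z), eye).numpy(), z)
    rot = ComplexLinearParams(np.zeros((4, 4)), np.eye(4))
    assert np.allclose(clinear(ct(z), rot).numpy(), 1j * z)


def test_clinear_worked_example():
    # W = [1+0i, 0+1i], b = 1+1i, input [1+1i, 1+0i] -> 2+3i
    w = np.array([[1 + 0j, 0 + 1j]])
    b = np.array([1 + 1j])
    x = np.array([[1 + 1j, 1 + 0j]])
    params = ComplexLinearParams(w.real, w.imag, b.real, b.imag)
    out = clinear(ct(x), params).numpy()
    expected = complex_linear_oracle(x, w, b)
    assert np.allclose(expected, [[2 + 3j]])
    assert np.allclose(out, expected)


def test_clinear_commutes_with_complex_scaling():
    z = rng.normal(size=(2, 5)) + 1j * rng.normal(size=(2, 5))
    w = rng.normal(size=(3, 5)) + 1j * rng.normal(size=(3, 5))
    params = ComplexLinearParams(w.real, w.imag)  # no bias
    alpha = -1.1 + 0.4j
    assert np.allclose(clinear(ct(alpha * z), params).numpy(),
                       alpha * clinear(ct(z), params).numpy())


def test_clinear_dimension_error():
    params = ComplexLinearParams(np.eye(3), np.zeros((3, 3)))
    with pytest.raises(DimensionError):
        clinear(ct(np.zeros((2, 4), dtype=complex)), params)


# ---------------------------------------------------------------------------
# cbatchnorm
# ---------------------------------------------------------------------------

def test_cbatchnorm_standardizes_each_part():
    params = ComplexBNParams.initialize(3)
    x = ct(rng.normal(2.0, 3.0, size=(16, 3, 4, 5))
           + 1j * rng.normal(-1.0, 0.5, size=(16, 3, 4, 5)))
    out = cbatchnorm(x, params, training=True)
    for part in (out.real.data, out.imag.data):
        assert np.allclose(part.mean(axis=(0, 2, 3)), 0, atol=1e-6)
        assert np.allclose(part.std(axis=(0, 2, 3)), 1, atol=1e-2)


def test_cbatchnorm_constant_input_maps_to_beta():
    params = ComplexBNParams.initialize(2)
    params.beta_real.data[:] = 5.0
    params.beta_imag.data[:] = 5.0
    x = ct(np.full((4, 2, 2, 2), 7 - 2j))
    out = cbatchnorm(x, params, training=True).numpy()
    assert np.allclose(out, 5 + 5j, atol=1e-6)


def test_cbatchnorm_imaginary_gamma_rotates():
    params = ComplexBNParams.initialize(1)
    params.gamma_real.data[:] = 0.0
    params.gamma_imag.data[:] = 1.0
    z = rng.normal(size=(32, 1, 2, 2)) + 1j * rng.normal(size=(32, 1, 2, 2))
    out = cbatchnorm(ct(z), params, training=True)
    # gamma = i applied to the standardized parts: (a + bi) -> (-b + ai)
    params2 = ComplexBNParams.initialize(1)
    std = cbatchnorm(ct(z), params2, training=True).numpy()
    assert np.allclose(out.numpy(), 1j * std, atol=1e-6)


def test_cbatchnorm_running_stats_and_inference():
    layer = CBatchNorm2d(2)
    x = ct(rng.normal(3.0, 2.0, size=(64, 2, 1, 8))
           + 1j * rng.normal(0.0, 1.0, size=(64, 2, 1, 8)))
    for _ in range(200):
        layer(x)
    layer.training = False
    out = layer(x)
    assert np.allclose(out.real.data.mean(axis=(0, 2, 3)), 0, atol=0.05)
    assert np.allclose(out.real.data.std(axis=(0, 2, 3)), 1, atol=0.05)


def test_cbatchnorm_degenerate_batch():
    params = ComplexBNParams.initialize(1)
    with pytest.raises(DegenerateBatchError):
        cbatchnorm(ct(np.zeros((1, 1, 2, 2), dtype=complex)), params, training=True)


# ---------------------------------------------------------------------------
# modulus
# ---------------------------------------------------------------------------

def test_modulus_examples():
    z = np.array([[3 + 4j, 0 + 0j, -5 - 12j]])
    out = modulus(ct(z)).data
    assert np.allclose(out, [[5.0, 0.0, 13.0]])


def test_modulus_rotation_invariance():
    z = rng.normal(size=(4, 6)) + 1j * rng.normal(size=(4, 6))
    base = modulus(ct(z)).data
    for theta in np.linspace(0, 2 * np.pi, 13):
        rotated = modulus(ct(np.exp(1j * theta) * z)).data
        assert np.allclose(rotated, base)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_modulus_absolute_homogeneity(seed):
    r = np.random.default_rng(seed)
    z = r.normal(size=(3, 4)) + 1j * r.normal(size=(3, 4))
    alpha = complex(r.normal(), r.normal())
    lhs = modulus(ct(alpha * z)).data
    rhs = abs(alpha) * modulus(ct(z)).data
    assert np.allclose(lhs, rhs)


def test_complex_tensor_shape_mismatch():
    with pytest.raises(DimensionError):
        ComplexTensor(np.zeros((2, 3)), np.zeros((3, 2)))
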