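"""Equation-level oracles and properties for the reconstruction blocks."""

import autograd
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rscdnet import nn
from rscdnet.core_blocks import (
    CRU,
    GateMasks,
    GroupNormParams,
    PlainBottleneck,
    SCRBlock,
    SCRBlockConfig,
    SRU,
    cru_fuse,
    default_gn_groups,
    group_normalize,
    informativeness_weights,
    spatial_gate,
    sru_forward,
    sru_reconstruct,
)
from rscdnet.nn import functional as F


# ---------------------------------------------------------------------------
# independent oracles (explicit index loops)
# ---------------------------------------------------------------------------

def gn_oracle(x, gamma, beta, groups, eps):
    n, c, h, w = x.shape
    out = np.empty_like(x)
    cg = c // groups
    for ni in range(n):
        for g in range(groups):
            sl = x[ni, g * cg:(g + 1) * cg]
            out[ni, g * cg:(g + 1) * cg] = (sl - sl.mean()) / np.sqrt(sl.var() + eps)
    for ci in range(c):
        out[:, ci] = out[:, ci] * gamma[ci] + beta[ci]
    return out


def sru_reconstruct_oracle(x, w1, w2):
    n, c, h, w = x.shape
    half = c // 2
    x1w = np.empty_like(x)
    x2w = np.empty_like(x)
    for idx in np.ndindex(x.shape):
        x1w[idx] = w1[idx] * x[idx]
        x2w[idx] = w2[idx] * x[idx]
    xw1 = x1w[:, :half] + x2w[:, half:]
    xw2 = x2w[:, :half] + x1w[:, half:]
    return np.concatenate([xw1, xw2], axis=1)


def fuse_oracle(y1, y2):
    n, c, h, w = y1.shape
    out = np.empty_like(y1)
    for ni in range(n):
        for ci in range(c):
            s1 = y1[ni, ci].mean()
            s2 = y2[ni, ci].mean()
            e1, e2 = np.exp(s1 - max(s1, s2)), np.exp(s2 - max(s1, s2))
            b1 = e1 / (e1 + e2)
            out[ni, ci] = b1 * y1[ni, ci] + (1 - b1) * y2[ni, ci]
    return out


# ---------------------------------------------------------------------------
# group_normalize
# ---------------------------------------------------------------------------

def test_gn_constant_groups_collapse_to_zero():
    x = np.ones((2, 4, 3, 3)) * 7.0
    params = GroupNormParams(np.ones(4), np.zeros(4), eps=1e-5, num_groups=2)
    np.testing.assert_allclose(group_normalize(x, params), 0.0, atol=1e-6)


def test_gn_two_point_analytic():
    # one group, one channel, values {1, 3}: normalize to {-1, 1}, then 2*xhat+1
    x = np.array([1.0, 3.0]).reshape(1, 1, 1, 2)
    params = GroupNormParams(np.array([2.0]), np.array([1.0]), eps=1e-12, num_groups=1)
    np.testing.assert_allclose(group_normalize(x, params),
                               np.array([-1.0, 3.0]).reshape(1, 1, 1, 2), atol=1e-5)


def test_gn_matches_loop_oracle(rng):
    x = rng.normal(size=(2, 4, 3, 3))
    gamma, beta = rng.normal(size=4), rng.normal(size=4)
    params = GroupNormParams(gamma, beta, eps=1e-6, num_groups=2)
    np.testing.assert_allclose(group_normalize(x, params),
                               gn_oracle(x, gamma, beta, 2, 1e-6), atol=1e-5)


def test_gn_validation_errors():
    x = np.zeros((1, 4, 2, 2))
    with pytest.raises(ValueError):
        GroupNormParams(np.ones(4), np.zeros(4), eps=-1.0, num_groups=2)
    with pytest.raises(ValueError):
        GroupNormParams(np.ones(4), np.zeros(4), num_groups=3)
    with pytest.raises(ValueError):
        group_normalize(x, GroupNormParams(np.ones(6), np.zeros(6), num_groups=2))


# ---------------------------------------------------------------------------
# informativeness_weights
# ---------------------------------------------------------------------------

def test_weights_symmetric_case():
    np.testing.assert_allclose(informativeness_weights(np.ones(4)), 0.25)


def test_weights_analytic():
    np.testing.assert_allclose(informativeness_weights(np.array([1.0, 3.0])),
                               [0.25, 0.75])


def test_weights_random_positive(rng):
    g = rng.uniform(0.1, 5.0, size=8)
    w = informativeness_weights(g)
    np.testing.assert_allclose(w, g / g.sum(), atol=1e-12)
    assert abs(w.sum() - 1.0) < 1e-12


def test_weights_negative_entries_use_magnitudes():
    g = np.array([1.0, -3.0])
    np.testing.assert_allclose(informativeness_weights(g), [0.25, 0.75])


def test_weights_zero_sum_raises():
    with pytest.raises(ValueError):
        informativeness_weights(np.zeros(3))


@given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=32))
@settings(max_examples=60, deadline=None)
def test_weights_sum_to_one_property(vals):
    w = informativeness_weights(np.array(vals))
    assert abs(float(np.sum(w)) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# spatial_gate
# ---------------------------------------------------------------------------

def test_gate_saturated_positive():
    masks = spatial_gate(np.full((1, 2, 2, 2), 10.0), 0.5)
    np.testing.assert_array_equal(masks.w1, 1.0)
    np.testing.assert_array_equal(masks.w2, 0.0)


def test_gate_tie_goes_non_informative():
    masks = spatial_gate(np.zeros((1, 2, 2, 2)), 0.5)  # sigmoid(0) == 0.5 exactly
    np.testing.assert_array_equal(masks.w1, 0.0)
    np.testing.assert_array_equal(masks.w2, 1.0)


def test_gate_complement_property(rng):
    masks = spatial_gate(rng.normal(size=(2, 4, 3, 3)), 0.5)
    np.testing.assert_array_equal(masks.w1 + masks.w2, 1.0)
    assert set(np.unique(masks.w1)) <= {0.0, 1.0}


@pytest.mark.parametrize("bad", [0.0, 1.0, -0.3, 1.5])
def test_gate_threshold_validation(bad):
    with pytest.raises(ValueError):
        spatial_gate(np.zeros((1, 2, 2, 2)), bad)


# ---------------------------------------------------------------------------
# sru_reconstruct
# ---------------------------------------------------------------------------

def _masks_like(x, w1):
    return GateMasks(w1=w1, w2=1.0 - w1, threshold=0.5)


def test_reconstruct_all_informative_is_identity(rng):
    x = rng.normal(size=(2, 4, 3, 3))
    out = sru_reconstruct(x, _masks_like(x, np.ones_like(x)))
    np.testing.assert_array_equal(out, x)


def test_reconstruct_all_non_informative_swaps_halves(rng):
    x = rng.normal(size=(2, 4, 3, 3))
    out = sru_reconstruct(x, _masks_like(x, np.zeros_like(x)))
    want = np.concatenate([x[:, 2:], x[:, :2]], axis=1)
    np.testing.assert_array_equal(out, want)


def test_reconstruct_matches_loop_oracle(rng):
    x = rng.normal(size=(1, 4, 2, 2))
    w1 = rng.integers(0, 2, size=x.shape).astype(float)
    out = sru_reconstruct(x, _masks_like(x, w1))
    np.testing.assert_array_equal(out, sru_reconstruct_oracle(x, w1, 1.0 - w1))


def test_reconstruct_odd_channels_rejected(rng):
    x = rng.normal(size=(1, 3, 2, 2))
    with pytest.raises(ValueError):
        sru_reconstruct(x, _masks_like(x, np.ones_like(x)))


# ---------------------------------------------------------------------------
# sru_forward
# ---------------------------------------------------------------------------

def test_sru_forward_equals_chained_ops(rng):
    x = rng.normal(size=(1, 4, 3, 3))
    params = GroupNormParams(rng.uniform(0.5, 2.0, 4), rng.normal(size=4),
                             eps=1e-5, num_groups=2)
    gn = group_normalize(x, params)
    w = informativeness_weights(params.gamma)
    masks = spatial_gate(w[None, :, None, None] * gn, 0.5)
    want = sru_reconstruct(x, masks)
    np.testing.assert_array_equal(sru_forward(x, params, 0.5), want)


def test_sru_forward_constant_input_swaps_masked_halves():
    # constant per group -> GN output = beta = 0 -> sigmoid = 0.5 -> all W2
    x = np.full((1, 4, 3, 3), 3.0)
    params = GroupNormParams(np.ones(4), np.zeros(4), num_groups=2)
    out = sru_forward(x, params, 0.5)
    want = np.concatenate([x[:, 2:], x[:, :2]], axis=1)
    np.testing.assert_array_equal(out, want)


def test_sru_forward_preserves_shape(rng):
    x = rng.normal(size=(3, 8, 5, 4))
    params = GroupNormParams(np.ones(8), np.zeros(8), num_groups=4)
    assert sru_forward(x, params, 0.5).shape == x.shape


def test_sru_module_shape_and_determinism(rng):
    sru = SRU(8, threshold=0.5)
    x = rng.normal(size=(2, 8, 4, 4))
    np.testing.assert_array_equal(sru(x), sru(x))
    assert sru(x).shape == x.shape


def test_default_gn_groups():
    assert default_gn_groups(64) == 16
    assert default_gn_groups(8) == 8
    assert default_gn_groups(6) == 6
    assert default_gn_groups(34) == 2


# ---------------------------------------------------------------------------
# CRU
# ---------------------------------------------------------------------------

def test_split_squeeze_channel_arithmetic(rng):
    cru = CRU(64, alpha=0.5, squeeze_ratio=2, rng=rng)
    up, low = cru.split_squeeze(rng.normal(size=(1, 64, 4, 4)))
    assert up.shape[1] == 16 and low.shape[1] == 16

    cru6 = CRU(6, alpha=0.5, squeeze_ratio=3, gwc_groups=1, rng=rng)
    up, low = cru6.split_squeeze(rng.normal(size=(1, 6, 4, 4)))
    assert up.shape[1] == 1 and low.shape[1] == 1


def test_split_squeeze_non_integral_rejected():
    with pytest.raises(ValueError):
        SCRBlockConfig(in_channels=5, mid_channels=5, out_channels=20, alpha=0.5)


def test_pwc_identity_kernel_is_identity(rng):
    cru = CRU(4, alpha=0.5, squeeze_ratio=2, gwc_groups=1, rng=rng)
    # 1-channel low branch; identity-initialize its completion conv
    x = rng.normal(size=(1, 1, 3, 3))
    w = np.zeros_like(cru.pwc_low.weight.data)
    w[0, 0, 0, 0] = 1.0
    cru.pwc_low.weight.data = w
    out = F.conv2d(x, cru.pwc_low.weight.data[:1, :1], None)
    np.testing.assert_allclose(out, x)


def test_gwc_groups1_matches_dense_conv(rng):
    cru = CRU(8, alpha=0.5, squeeze_ratio=2, gwc_groups=1, rng=rng)
    up = rng.normal(size=(2, 2, 5, 5))
    got = F.conv2d(up, cru.gwc.weight.data, None, padding=1, groups=1)
    from test_nn import conv2d_oracle

    want = conv2d_oracle(up, cru.gwc.weight.data, None, 1, 1, 1)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_transform_channel_extents(rng):
    cru = CRU(32, alpha=0.5, squeeze_ratio=2, gwc_groups=2, rng=rng)
    up, low = cru.split_squeeze(rng.normal(size=(1, 32, 4, 4)))
    y1, y2 = cru.transform(up, low)
    assert y1.shape[1] == 32 and y2.shape[1] == 32
    assert y1.shape == y2.shape


def test_cru_stride_halves_spatial(rng):
    cru = CRU(8, stride=2, rng=rng)
    out = cru(rng.normal(size=(1, 8, 8, 8)))
    assert out.shape == (1, 8, 4, 4)


# ---------------------------------------------------------------------------
# cru_fuse
# ---------------------------------------------------------------------------

def test_fuse_equal_branches_is_mean(rng):
    y = rng.normal(size=(2, 3, 2, 2))
    np.testing.assert_allclose(cru_fuse(y, y), y, atol=1e-12)


def test_fuse_saturates_toward_dominant_branch(rng):
    y1 = rng.normal(size=(1, 3, 2, 2)) + 50.0
    y2 = rng.normal(size=(1, 3, 2, 2)) - 50.0
    np.testing.assert_allclose(cru_fuse(y1, y2), y1, atol=1e-6)


def test_fuse_matches_loop_oracle(rng):
    y1 = rng.normal(size=(2, 3, 2, 2))
    y2 = rng.normal(size=(2, 3, 2, 2))
    np.testing.assert_allclose(cru_fuse(y1, y2), fuse_oracle(y1, y2), atol=1e-6)


def test_fuse_convex_combination_property(rng):
    y1 = rng.normal(size=(2, 4, 3, 3))
    y2 = rng.normal(size=(2, 4, 3, 3))
    out = cru_fuse(y1, y2)
    lo = np.minimum(y1, y2) - 1e-12
    hi = np.maximum(y1, y2) + 1e-12
    assert np.all(out >= lo) and np.all(out <= hi)


def test_fuse_shape_mismatch(rng):
    with pytest.raises(ValueError):
        cru_fuse(rng.normal(size=(1, 2, 2, 2)), rng.normal(size=(1, 3, 2, 2)))


# ---------------------------------------------------------------------------
# SCRBlock
# ---------------------------------------------------------------------------

def _block_cfg(stride=1, in_ch=16, mid=4):
    return SCRBlockConfig(in_channels=in_ch, mid_channels=mid,
                          out_channels=4 * mid, stride=stride, gwc_groups=1)


def test_block_shape_stride1(rng):
    blk = SCRBlock(_block_cfg(), rng=rng)
    out = blk(rng.normal(size=(2, 16, 8, 8)))
    assert out.shape == (2, 16, 8, 8)
    assert np.isfinite(out).all()


def test_block_shape_stride2(rng):
    blk = SCRBlock(_block_cfg(stride=2), rng=rng)
    out = blk(rng.normal(size=(1, 16, 8, 8)))
    assert out.shape == (1, 16, 4, 4)


@pytest.mark.parametrize("cls", [SCRBlock, PlainBottleneck])
def test_block_input_gradient_matches_finite_difference(rng, cls):
    blk = cls(_block_cfg(in_ch=8, mid=4), rng=rng)
    blk.eval()  # freeze batch statistics so FD perturbs only the input path
    x = rng.normal(size=(1, 8, 8, 8))
    tgt = rng.normal(size=(1, 16, 8, 8))  # block output is 4x the bottleneck width

    import autograd.numpy as anp

    def loss_fn(inp):
        return anp.sum((blk(inp) - tgt) ** 2)

    g = autograd.grad(loss_fn)(x)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (0, 3, 4, 4), (0, 7, 7, 7), (0, 5, 2, 6)]:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        fd = (float(loss_fn(xp)) - float(loss_fn(xm))) / (2 * eps)
        np.testing.assert_allclose(g[idx], fd, rtol=1e-3, atol=1e-6)


def test_block_invalid_config_rejected():
    with pytest.raises(ValueError):
        SCRBlockConfig(in_channels=8, mid_channels=4, out_channels=4 * 4, stride=3)
    with pytest.raises(ValueError):
        SCRBlockConfig(in_channels=8, mid_channels=4, out_channels=4 * 4,
                       gate_threshold=1.2)


def test_block_channel_mismatch_rejected(rng):
    blk = SCRBlock(_block_cfg(), rng=rng)
    with pytest.raises(ValueError):
        blk(rng.normal(size=(1, 7, 8, 8)))


def test_block_1x1_spatial_input_legal(rng):
    blk = SCRBlock(_block_cfg(), rng=rng)
    out = blk(rng.normal(size=(2, 16, 1, 1)))
    assert out.shape == (2, 16, 1, 1)
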