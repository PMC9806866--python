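"""Fusion blocks vs scalar arithmetic and nested-loop oracles."""

import math

import numpy as np
import pytest

from metafuse.fusion import (ConcatFusion, MDNet, MDNetParams, MetaBlock,
                             MetaBlockParams, MetaNet, MetaNetParams, NoFusion,
                             concat_fuse, f_b, g_b, make_fusion, mdnet_fuse,
                             metablock_forward, metanet_forward, sigmoid_gate,
                             tanh_gate)
from metafuse.nn import Tensor


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def random_metablock_params(rng, d_meta, k_img):
    return MetaBlockParams(rng.normal(size=(d_meta, k_img)),
                           rng.normal(size=(d_meta, k_img)),
                           rng.normal(size=k_img), rng.normal(size=k_img))


def random_metanet_params(rng, d_meta, k_img, hidden=None):
    h = hidden or d_meta
    return MetaNetParams(rng.normal(size=(d_meta, h)), rng.normal(size=h),
                         rng.normal(size=(h, k_img)), rng.normal(size=k_img))


def loop_metablock(X, M, p):
    """Quadruple-nested scalar reference for the gated block."""
    n, k, h, w = X.shape
    out = np.empty_like(X)
    for b in range(n):
        for c in range(k):
            f = sum(p.W_f[d, c] * M[b, d] for d in range(p.d_meta)) + p.w_0f[c]
            g = sum(p.W_g[d, c] * M[b, d] for d in range(p.d_meta)) + p.w_0g[c]
            for i in range(h):
                for j in range(w):
                    out[b, c, i, j] = _sigmoid(math.tanh(f * X[b, c, i, j]) + g)
    return out


def loop_metanet(X, M, p):
    n, k, h, w = X.shape
    out = np.empty_like(X)
    for b in range(n):
        hid = np.maximum(M[b] @ p.W1 + p.b1, 0.0)
        s = _sigmoid(hid @ p.W2 + p.b2)
        for c in range(k):
            for i in range(h):
                for j in range(w):
                    out[b, c, i, j] = s[c] * X[b, c, i, j]
    return out


# ------------------------------------------------------------ f_b / g_b

def test_fb_gb_scalar_cases():
    p = MetaBlockParams(np.array([[1.0], [2.0]]), np.zeros((2, 1)),
                        np.array([0.5]), np.array([0.25]))
    assert np.allclose(f_b(np.array([1.0, 0.0]), p), [1.5])
    # all-zero metadata returns the bias exactly
    assert np.allclose(f_b(np.zeros(2), p), [0.5])
    assert np.allclose(g_b(np.zeros(2), p), [0.25])


def test_fb_zero_params_zero_output():
    p = MetaBlockParams(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros(2), np.zeros(2))
    assert np.allclose(f_b(np.array([1.0, 0.0, 1.0]), p), 0.0)


def test_gb_matches_hand_matrix_vector(rng):
    p = random_metablock_params(rng, 2, 2)
    x = np.array([1.0, 2.0])
    assert np.allclose(g_b(x, p), p.W_g.T @ x + p.w_0g)


def test_fb_shape_mismatch_error(rng):
    p = random_metablock_params(rng, 3, 2)
    with pytest.raises(ValueError):
        f_b(np.zeros(4), p)


# ---------------------------------------------------------------- gates

def test_tanh_gate_scalar_and_range(rng):
    X = np.ones((1, 1, 1, 1))
    assert np.allclose(tanh_gate(X, np.array([1.0])), math.tanh(1.0))
    assert np.allclose(tanh_gate(X, np.array([0.0])), 0.0)
    out = tanh_gate(rng.normal(size=(2, 3, 4, 4)), rng.normal(size=3))
    assert np.all(np.abs(out) < 1.0)


def test_sigmoid_gate_scalar_and_range(rng):
    T = np.zeros((1, 2, 2, 2))
    assert np.allclose(sigmoid_gate(T, np.zeros(2)), 0.5)
    t1 = np.full((1, 1, 1, 1), math.tanh(1.0))
    assert np.allclose(sigmoid_gate(t1, np.zeros(1)), _sigmoid(math.tanh(1.0)))
    out = sigmoid_gate(rng.normal(size=(2, 3, 4, 4)), rng.normal(size=3))
    assert np.all((out > 0.0) & (out < 1.0))
    # large additive modifier drives outputs towards 1 monotonically
    lo = sigmoid_gate(T, np.full(2, 5.0))
    hi = sigmoid_gate(T, np.full(2, 25.0))
    assert np.all(hi >= lo) and np.all(hi < 1.0)


def test_gate_channel_mismatch_error(rng):
    with pytest.raises(ValueError):
        tanh_gate(np.zeros((1, 3, 2, 2)), np.zeros(4))
    with pytest.raises(ValueError):
        sigmoid_gate(np.zeros((1, 3, 2, 2)), np.zeros(2))


# ------------------------------------------------------------ metablock

def test_metablock_zero_params_gives_half(rng):
    p = MetaBlockParams(np.zeros((3, 2)), np.zeros((3, 2)), np.zeros(2), np.zeros(2))
    out = metablock_forward(rng.normal(size=(2, 2, 3, 3)), rng.random((2, 3)), p)
    assert np.allclose(out, 0.5)


def test_metablock_scalar_composition():
    p = MetaBlockParams(np.array([[1.0]]), np.array([[0.0]]),
                        np.array([0.0]), np.array([0.0]))
    out = metablock_forward(np.ones((1, 1, 1, 1)), np.ones((1, 1)), p)
    assert np.allclose(out, _sigmoid(math.tanh(1.0)))
    assert abs(out.item() - 0.6817) < 1e-4


def test_metablock_matches_loop_oracle(rng):
    X = rng.normal(size=(2, 3, 4, 4))
    M = rng.normal(size=(2, 5))
    p = random_metablock_params(rng, 5, 3)
    out = metablock_forward(X, M, p)
    assert out.shape == X.shape
    assert np.allclose(out, loop_metablock(X, M, p), rtol=1e-5, atol=1e-12)


def test_metablock_equals_gate_composition(rng):
    X = rng.normal(size=(2, 3, 4, 4))
    M = rng.normal(size=(2, 5))
    p = random_metablock_params(rng, 5, 3)
    composed = sigmoid_gate(tanh_gate(X, f_b(M, p)), g_b(M, p))
    assert np.allclose(metablock_forward(X, M, p), composed)


# -------------------------------------------------------------- metanet

def test_metanet_zero_params_halves_input(rng):
    p = MetaNetParams(np.zeros((3, 3)), np.zeros(3), np.zeros((3, 2)), np.zeros(2))
    X = rng.normal(size=(2, 2, 3, 3))
    assert np.allclose(metanet_forward(X, rng.random((2, 3)), p), 0.5 * X)


def test_metanet_absorbs_zero_images(rng):
    p = random_metanet_params(rng, 3, 2)
    out = metanet_forward(np.zeros((2, 2, 3, 3)), rng.random((2, 3)), p)
    assert np.allclose(out, 0.0)


def test_metanet_matches_loop_oracle(rng):
    X = rng.normal(size=(2, 3, 4, 4))
    M = rng.normal(size=(2, 5))
    p = random_metanet_params(rng, 5, 3, hidden=4)
    out = metanet_forward(X, M, p)
    assert out.shape == X.shape
    assert np.allclose(out, loop_metanet(X, M, p), rtol=1e-5, atol=1e-12)


def test_metanet_scale_bounds_and_sign(rng):
    X = rng.normal(size=(2, 3, 4, 4))
    p = random_metanet_params(rng, 5, 3)
    out = metanet_forward(X, rng.normal(size=(2, 5)), p)
    assert np.all(np.abs(out) <= np.abs(X))
    nonzero = X != 0
    assert np.all(np.sign(out[nonzero]) == np.sign(X[nonzero]))


# ---------------------------------------------------------------- mdnet

def random_mdnet_params(rng, d_meta, k_img, d_fuse):
    return MDNetParams(random_metanet_params(rng, d_meta, k_img),
                       random_metablock_params(rng, d_meta, k_img),
                       rng.normal(size=(k_img, d_fuse)), rng.normal(size=d_fuse),
                       rng.normal(size=(k_img, d_fuse)), rng.normal(size=d_fuse))


def test_mdnet_matches_composition_of_blocks(rng):
    d_meta, k_img, d_fuse = 4, 3, 2
    p = random_mdnet_params(rng, d_meta, k_img, d_fuse)
    X = rng.normal(size=(2, k_img, 4, 4))
    M = rng.normal(size=(2, d_meta))
    fused = mdnet_fuse(X, M, p)
    assert fused.shape == (2, 2 * d_fuse)
    pool = lambda A: A.mean(axis=(2, 3))
    zn = pool(metanet_forward(X, M, p.metanet)) @ p.P_net + p.bp_net
    zb = pool(metablock_forward(X, M, p.metablock)) @ p.P_block + p.bp_block
    assert np.allclose(fused, np.concatenate([zn, zb], axis=1), rtol=1e-10)
    # sum mode adds the two projected streams instead
    assert np.allclose(mdnet_fuse(X, M, p, mode="sum"), zn + zb, rtol=1e-10)


def test_mdnet_identity_projections(rng):
    d_meta, k_img = 3, 4
    p = MDNetParams(random_metanet_params(rng, d_meta, k_img),
                    random_metablock_params(rng, d_meta, k_img),
                    np.eye(k_img), np.zeros(k_img), np.eye(k_img), np.zeros(k_img))
    X = rng.normal(size=(2, k_img, 2, 2))
    M = rng.normal(size=(2, d_meta))
    fused = mdnet_fuse(X, M, p)
    assert np.allclose(fused[:, :k_img], metanet_forward(X, M, p.metanet).mean(axis=(2, 3)))
    assert np.allclose(fused[:, k_img:], metablock_forward(X, M, p.metablock).mean(axis=(2, 3)))


def test_mdnet_default_fuse_dimension(rng):
    block = MDNet(4, 5, rng=rng)
    assert block.d_fuse == 3  # ceil(5 / 2)
    assert block.out_dim == 6


# ------------------------------------------------------------- baselines

def test_concat_fuse_shapes_and_pooling(rng):
    X = rng.normal(size=(3, 4, 2, 2))
    M = rng.random((3, 2))
    out = concat_fuse(X, M)
    assert out.shape == (3, 6)
    assert np.allclose(out[:, :4], X.mean(axis=(2, 3)))
    zeroed = concat_fuse(X, np.zeros((3, 2)))
    assert np.allclose(zeroed[:, 4:], 0.0)


def test_pooled_values_equal_spatial_mean_loop(rng):
    X = rng.normal(size=(2, 3, 4, 4))
    out = concat_fuse(X, np.zeros((2, 1)))
    for b in range(2):
        for c in range(3):
            acc = sum(X[b, c, i, j] for i in range(4) for j in range(4)) / 16
            assert np.isclose(out[b, c], acc)


# ------------------------------------------------------------ properties

def test_metadata_sensitivity(rng):
    """Distinct one-hot metadata must change the output of every fusion block."""
    d_meta, k_img = 4, 3
    X = rng.normal(size=(1, k_img, 4, 4))
    m1, m2 = np.zeros((1, d_meta)), np.zeros((1, d_meta))
    m1[0, 0] = 1.0
    m2[0, 1] = 1.0
    pb = random_metablock_params(rng, d_meta, k_img)
    pn = random_metanet_params(rng, d_meta, k_img)
    assert not np.allclose(metablock_forward(X, m1, pb), metablock_forward(X, m2, pb))
    assert not np.allclose(metanet_forward(X, m1, pn), metanet_forward(X, m2, pn))


def test_batch_independence(rng):
    X = rng.normal(size=(4, 3, 4, 4))
    M = rng.normal(size=(4, 5))
    pb = random_metablock_params(rng, 5, 3)
    pn = random_metanet_params(rng, 5, 3)
    pm = random_mdnet_params(rng, 5, 3, 2)
    for fwd, p in [(metablock_forward, pb), (metanet_forward, pn),
                   (lambda x, m, q: mdnet_fuse(x, m, q), pm)]:
        batch = fwd(X, M, p)
        singles = np.stack([fwd(X[i:i + 1], M[i:i + 1], p)[0] for i in range(4)])
        assert np.allclose(batch, singles, rtol=1e-10)


def test_block_channel_mismatch_errors(rng):
    X = Tensor(rng.normal(size=(1, 5, 2, 2)))
    M = Tensor(rng.random((1, 3)))
    for block in [MetaBlock(3, 4, rng), MetaNet(3, 4, rng=rng),
                  ConcatFusion(3, 4), NoFusion(3, 4)]:
        with pytest.raises(ValueError):
            block(X, M)


def test_make_fusion_registry(rng):
    for name in ("mdnet", "metanet", "metablock", "concat", "none"):
        block = make_fusion(name, 4, 6, rng=rng)
        assert hasattr(block, "out_dim")
    with pytest.raises(ValueError, match="unknown fusion"):
        make_fusion("attention", 4, 6)
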