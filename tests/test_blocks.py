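"""Unit and oracle tests for the three block types."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from lgmanet import nn
from lgmanet.blocks import Emra, Lgipb, ShiftedMlpBlock, eca_kernel_size
from lgmanet.config import EmraConfig, LgipbConfig, ShiftedMlpConfig
from lgmanet.nn import Tensor


# ---------------------------------------------------------------------
# adaptive kernel size
# ---------------------------------------------------------------------

@pytest.mark.parametrize("c, gamma, b, expected", [
    (256, 2, 1, 5),   # t = floor(9/2) = 4, even -> 5
    (2, 2, 1, 1),     # t = floor(2/2) = 1, odd
    (48, 2, 1, 3),    # t = floor(6.585/2) = 3, odd
    (1, 2, 1, 1),     # t = 0 -> clamp to 1
])
def test_eca_kernel_size_hand_traces(c, gamma, b, expected):
    assert eca_kernel_size(c, gamma, b) == expected


def test_eca_kernel_size_rejects_bad_args():
    with pytest.raises(ValueError):
        eca_kernel_size(0)
    with pytest.raises(ValueError):
        eca_kernel_size(8, gamma=0)


def test_eca_kernel_size_monotone_and_odd():
    ks = [eca_kernel_size(c, 2.0, 1.0) for c in range(1, 1025)]
    assert all(k % 2 == 1 and k >= 1 for k in ks)
    assert all(k2 >= k1 for k1, k2 in zip(ks, ks[1:]))


# ---------------------------------------------------------------------
# oracle helpers: plain NumPy / SciPy compositions
# ---------------------------------------------------------------------

def np_conv(x, w, b=None):
    """Reference 2-D correlation (scipy) for a (B,C,H,W) batch."""
    B, Cin, H, W = x.shape
    Cout = w.shape[0]
    out = np.zeros((B, Cout, H, W))
    for bi in range(B):
        for co in range(Cout):
            for ci in range(Cin):
                out[bi, co] += correlate(x[bi, ci].astype(np.float64),
                                         w[co, ci].astype(np.float64),
                                         mode="constant", cval=0.0)
            if b is not None:
                out[bi, co] += b[co]
    return out


def np_bn_eval(x, bn):
    scale = bn.weight.data / np.sqrt(bn.running_var + bn.eps)
    shift = bn.bias.data - bn.running_mean * scale
    return x * scale.reshape(1, -1, 1, 1) + shift.reshape(1, -1, 1, 1)


def np_prelu(x, alpha):
    a = alpha.reshape(1, -1, 1, 1)
    return np.where(x > 0, x, a * x)


# ---------------------------------------------------------------------
# LGIPB
# ---------------------------------------------------------------------

def test_lgipb_channel_trace_and_output_shape():
    block = Lgipb(LgipbConfig(3, 16))
    x = Tensor(np.random.default_rng(0).standard_normal((2, 3, 64, 64)).astype(np.float32))
    out, trace = block.forward_trace(x)
    assert [t.shape[1] for t in trace] == [12, 12, 24, 48]
    assert [t.shape for t in trace] == [(2, 12, 64, 64), (2, 12, 64, 64),
                                        (2, 24, 64, 64), (2, 48, 64, 64)]
    assert out.shape == (2, 16, 64, 64)
    assert np.isfinite(out.data).all()


def test_lgipb_identity_channel_case():
    block = Lgipb(LgipbConfig(12, 12))
    x = Tensor(np.zeros((1, 12, 8, 8), np.float32))
    assert block(x).shape == (1, 12, 8, 8)


def test_lgipb_channel_mismatch_names_both_values():
    block = Lgipb(LgipbConfig(3, 16))
    with pytest.raises(ValueError, match="3.*7|7.*3"):
        block(Tensor(np.zeros((1, 7, 8, 8), np.float32)))


def test_lgipb_matches_step_by_step_composition():
    """Brute-force oracle: assemble the dense flow step by step from
    primitive SciPy/NumPy ops with the block's own weights (eval-mode BN)."""
    nn.seed_all(42)
    block = Lgipb(LgipbConfig(3, 10)).eval()
    x = np.random.default_rng(3).standard_normal((1, 3, 16, 16)).astype(np.float32)

    x1 = np_conv(x, block.conv1.weight.data, block.conv1.bias.data)
    s = block.stage2
    x2 = np_prelu(np_bn_eval(np_conv(x1, s.conv.weight.data), s.bn), s.act.weight.data)
    s = block.stage3
    x3 = np_prelu(np_bn_eval(np_conv(np.concatenate([x1, x2], 1), s.conv.weight.data), s.bn),
                  s.act.weight.data)
    s = block.stage4
    x4 = np_prelu(np_bn_eval(np_conv(np.concatenate([x1, x2, x3], 1), s.conv.weight.data), s.bn),
                  s.act.weight.data)
    s = block.stage_out
    expect = np_prelu(np_bn_eval(np_conv(x4, s.conv.weight.data), s.bn), s.act.weight.data)

    got = block(Tensor(x)).data
    np.testing.assert_allclose(got, expect, atol=1e-5, rtol=1e-5)


def test_lgipb_gradient_reaches_every_parameter():
    nn.seed_all(7)
    block = Lgipb(LgipbConfig(3, 8))
    x = Tensor(np.random.default_rng(0).standard_normal((2, 3, 12, 12)).astype(np.float32))
    block(x).sum().backward()
    for name, p in block.named_parameters():
        assert p.grad is not None, f"no gradient reached {name}"
        assert np.any(p.grad != 0) or p.size == 0, f"zero gradient at {name}"


# ---------------------------------------------------------------------
# EMRA
# ---------------------------------------------------------------------

def test_emra_shapes_and_concat_width():
    nn.seed_all(0)
    emra = Emra(EmraConfig(32, 32))
    x = Tensor(np.random.default_rng(1).standard_normal((2, 32, 24, 24)).astype(np.float32))
    xw = nn.mul(x, emra.attention(x))
    assert xw.shape == (2, 32, 24, 24)
    feats = nn.concat([br(xw) for br in emra.branches.layers], axis=1)
    assert feats.shape == (2, 128, 24, 24)  # 4 * C_in
    assert emra(x).shape == (2, 32, 24, 24)


def test_emra_attention_weights_in_unit_interval():
    nn.seed_all(0)
    emra = Emra(EmraConfig(48, 48))
    x = Tensor(np.random.default_rng(2).standard_normal((3, 48, 8, 8)).astype(np.float32))
    w = emra.attention(x).data
    assert w.shape == (3, 48, 1, 1)
    assert np.all(w > 0) and np.all(w < 1)


def test_emra_all_ones_attention_equals_pure_fusion_oracle():
    """With the attention branch forced to ones, the module must equal the
    plain multi-scale fusion, independently composed with SciPy."""
    nn.seed_all(11)
    emra = Emra(EmraConfig(6, 5)).eval()
    x = np.random.default_rng(5).standard_normal((2, 6, 10, 10)).astype(np.float32)

    emra.attention = lambda t: Tensor(np.ones((2, 6, 1, 1), np.float32))
    got = emra(Tensor(x)).data

    feats = [np_conv(x, br.weight.data, br.bias.data) for br in emra.branches.layers]
    expect = np_conv(np.concatenate(feats, 1), emra.fuse.weight.data, emra.fuse.bias.data)
    np.testing.assert_allclose(got, expect, atol=1e-4, rtol=1e-4)


def test_emra_limit_case_reduces_to_1x1_conv():
    """kernels=(1,), identity fusion, all-ones attention: the module is a
    single 1x1 convolution."""
    nn.seed_all(3)
    emra = Emra(EmraConfig(4, 4, kernel_sizes=(1,)))
    emra.fuse.weight.data[...] = np.eye(4, dtype=np.float32).reshape(4, 4, 1, 1)
    emra.fuse.bias.data[...] = 0
    emra.attention = lambda t: Tensor(np.ones((1, 4, 1, 1), np.float32))
    x = np.random.default_rng(9).standard_normal((1, 4, 7, 7)).astype(np.float32)
    got = emra(Tensor(x)).data
    branch = emra.branches.layers[0]
    expect = np_conv(x, branch.weight.data, branch.bias.data)
    np.testing.assert_allclose(got, expect, atol=1e-5)


def test_emra_channel_mismatch_raises():
    emra = Emra(EmraConfig(8, 8))
    with pytest.raises(ValueError, match="8"):
        emra(Tensor(np.zeros((1, 4, 6, 6), np.float32)))


# ---------------------------------------------------------------------
# shifted MLP
# ---------------------------------------------------------------------

def test_shifted_mlp_preserves_shape():
    nn.seed_all(0)
    block = ShiftedMlpBlock(ShiftedMlpConfig(160))
    x = Tensor(np.random.default_rng(0).standard_normal((2, 160, 16, 16)).astype(np.float32))
    assert block(x).shape == (2, 160, 16, 16)


def test_shifted_mlp_deterministic_without_dropout():
    nn.seed_all(0)
    block = ShiftedMlpBlock(ShiftedMlpConfig(12, drop_rate=0.0))
    x = Tensor(np.random.default_rng(1).standard_normal((1, 12, 8, 8)).astype(np.float32))
    a = block(x).data
    b = block(x).data
    np.testing.assert_array_equal(a, b)


def test_shifted_mlp_zero_weights_is_identity():
    nn.seed_all(0)
    block = ShiftedMlpBlock(ShiftedMlpConfig(6, drop_rate=0.0))
    for _, p in block.fc1.named_parameters():
        p.data[...] = 0
    for _, p in block.fc2.named_parameters():
        p.data[...] = 0
    for _, p in block.dwconv.named_parameters():
        p.data[...] = 0
    x = np.random.default_rng(2).standard_normal((2, 6, 9, 9)).astype(np.float32)
    np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-6)


# ---------------------------------------------------------------------
# shared spatial-preservation property
# ---------------------------------------------------------------------

@pytest.mark.parametrize("shape", [(1, 3, 8, 8), (2, 3, 17, 33), (1, 3, 1, 1),
                                   (2, 3, 64, 8)])
def test_blocks_preserve_spatial_dims(shape):
    nn.seed_all(0)
    lg = Lgipb(LgipbConfig(3, 6))
    em = Emra(EmraConfig(3, 6))
    ml = ShiftedMlpBlock(ShiftedMlpConfig(3))
    x = Tensor(np.random.default_rng(0).standard_normal(shape).astype(np.float32))
    for block in (lg, em, ml):
        out = block(x)
        assert out.shape[2:] == shape[2:], type(block).__name__
        assert np.isfinite(out.data).all()
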