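"""Oracle and invariant tests for the Transformer-side blocks.

The two load-bearing checks are brute-force oracles: TMSA reduced to a
single head with no spatial reduction and identity projections must equal
textbook softmax(X X^T / sqrt(d)) X self-attention, and one criss-cross
position-attention pass must match an explicit per-pixel double loop over
each pixel's row and column.
"""

import numpy as np
import pytest

from vesselseg.attention import (
    AttentionConfig,
    PatchEmbed,
    PositionAttention,
    PositionalEncoding,
    TMSA,
    TPABlock,
)
from vesselseg.nn.tensor import Tensor

rng = np.random.default_rng(7)


def _freeze_identity_conv1x1(conv):
    d = conv.weight.data.shape[0]
    conv.weight.data = np.eye(d).reshape(d, d, 1, 1)
    conv.bias.data = np.zeros(d)


def _softmax_np(e, axis=-1):
    e = e - e.max(axis=axis, keepdims=True)
    x = np.exp(e)
    return x / x.sum(axis=axis, keepdims=True)


class TestPatchEmbed:
    @pytest.mark.parametrize("cin,h,w", [(64, 16, 16), (32, 64, 64)])
    def test_halves_side_and_doubles_channels(self, cin, h, w):
        pe = PatchEmbed(cin, rng=np.random.default_rng(0))
        out = pe(Tensor(rng.normal(size=(1, cin, h, w))))
        assert out.shape == (1, 2 * cin, h // 2, w // 2)

    def test_sigmoid_gate_bounds_magnitude(self):
        pe = PatchEmbed(4, rng=np.random.default_rng(1))
        x = Tensor(rng.normal(size=(2, 4, 8, 8)))
        out = pe(x).data
        xp = pe.proj(pe.bn(x)).data
        assert np.all(np.abs(out) <= np.abs(xp) + 1e-12)

    def test_odd_spatial_dims_rejected(self):
        pe = PatchEmbed(2)
        with pytest.raises(ValueError, match="even"):
            pe(Tensor(np.zeros((1, 2, 5, 6))))


class TestPositionalEncoding:
    def test_shape_preserved_and_zero_fixed_point(self):
        enc = PositionalEncoding(3, rng=np.random.default_rng(2))
        x = rng.normal(size=(2, 3, 5, 7))
        assert enc(Tensor(x)).shape == (2, 3, 5, 7)
        assert np.all(enc(Tensor(np.zeros_like(x))).data == 0)

    def test_gate_factor_in_unit_interval(self):
        enc = PositionalEncoding(3, rng=np.random.default_rng(3))
        x = rng.normal(size=(1, 3, 4, 4)) + 1.0
        from vesselseg.nn.tensor import sigmoid

        gate = sigmoid(enc.dw(Tensor(x))).data
        assert np.all((gate > 0) & (gate < 1))


class TestTMSA:
    def test_softmax_rows_sum_to_one(self):
        cfg = AttentionConfig(d_m=8, heads=2, sr_ratio=2)
        att = TMSA(cfg, rng=np.random.default_rng(4))
        amap = att.attention_map(Tensor(rng.normal(size=(1, 8, 4, 6))))
        assert np.allclose(amap.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(amap >= 0)

    @pytest.mark.parametrize("cfg", [AttentionConfig(8, 2, 2), AttentionConfig(6, 1, 1), AttentionConfig(8, 4, 1, 2)])
    def test_output_shape_equals_input_shape(self, cfg):
        att = TMSA(cfg, rng=np.random.default_rng(5))
        x = Tensor(rng.normal(size=(2, cfg.d_m, 4, 4)))
        assert att(x).shape == x.shape

    def test_identity_freeze_matches_vanilla_self_attention(self):
        d, h, w = 6, 4, 5
        att = TMSA(AttentionConfig(d_m=d, heads=1, sr_ratio=1), rng=np.random.default_rng(6))
        for conv in (att.q_proj, att.k_proj, att.v_proj):
            _freeze_identity_conv1x1(conv)
        att.out_proj.weight.data = np.eye(d)
        att.out_proj.bias.data = np.zeros(d)
        att.head_mix_weight.data = np.eye(1)
        att.head_mix_bias.data = np.zeros(1)
        att.attn_norm.enabled = False
        x = rng.normal(size=(1, d, h, w))
        got = att.core(Tensor(x)).data[0]
        tokens = x[0].reshape(d, h * w).T  # (n, d)
        attn = _softmax_np(tokens @ tokens.T / np.sqrt(d))
        ref = (attn @ tokens).T.reshape(d, h, w)
        assert np.allclose(got, ref, atol=1e-4)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            AttentionConfig(d_m=6, heads=4).validate()


def crisscross_oracle(module: PositionAttention, x: np.ndarray) -> np.ndarray:
    """Explicit double loop over every pixel's row and column."""

    def conv1x1(conv, arr):
        w = conv.weight.data[:, :, 0, 0]
        return np.einsum("oc,chw->ohw", w, arr) + conv.bias.data[:, None, None]

    _, c, hh, ww = x.shape
    m = conv1x1(module.m_proj, x[0])
    nf = conv1x1(module.n_proj, x[0])
    v = conv1x1(module.v_proj, x[0])
    out = np.zeros_like(x[0])
    for i in range(hh):
        for j in range(ww):
            slots = [(a, j) for a in range(hh)] + [(i, b) for b in range(ww) if b != j]
            q = m[:, i, j]
            energies = np.array([q @ nf[:, a, b] for a, b in slots])
            weights = _softmax_np(energies)
            agg = sum(wt * v[:, a, b] for wt, (a, b) in zip(weights, slots))
            out[:, i, j] = agg + x[0, :, i, j]
    return out[None]


class TestPositionAttention:
    def test_single_pixel_map_returns_value_plus_residual(self):
        pa = PositionAttention(3, rng=np.random.default_rng(8))
        x = Tensor(rng.normal(size=(1, 3, 1, 1)))
        got = pa(x).data
        expected = pa.v_proj(x).data + x.data
        assert np.allclose(got, expected, atol=1e-10)

    def test_weights_sum_to_one_over_crisscross_slots(self):
        pa = PositionAttention(4, rng=np.random.default_rng(9))
        amap = pa.attention_map(Tensor(rng.normal(size=(1, 4, 5, 6))))
        assert np.allclose(amap.sum(axis=-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("h,w", [(4, 5), (8, 8), (8, 3), (2, 2)])
    def test_matches_double_loop_oracle(self, h, w):
        pa = PositionAttention(3, rng=np.random.default_rng(10))
        x = rng.normal(size=(1, 3, h, w))
        got = pa(Tensor(x)).data
        assert np.allclose(got, crisscross_oracle(pa, x), atol=1e-5)


class TestTPABlock:
    def test_shape_preserved(self):
        block = TPABlock(AttentionConfig(8, 2, 2), rng=np.random.default_rng(11))
        x = Tensor(rng.normal(size=(2, 8, 6, 6)))
        assert block(x).shape == x.shape

    def test_deterministic_under_fixed_weights(self):
        block = TPABlock(AttentionConfig(4, 1, 1), rng=np.random.default_rng(12))
        x = Tensor(rng.normal(size=(1, 4, 5, 5)))
        a = block(x).data
        b = block(x).data
        assert np.array_equal(a, b)

    def test_two_pass_crisscross_reaches_every_pixel_pair(self):
        block = TPABlock(AttentionConfig(4, 1, 1), rng=np.random.default_rng(13))
        x = rng.normal(size=(1, 4, 6, 6))
        from vesselseg.nn.tensor import narrow

        for pi in range(6):
            for pj in range(6):
                xt = Tensor(x, requires_grad=True)
                out = block(xt)
                pixel = narrow(narrow(out, 2, pi, 1), 3, pj, 1)
                pixel.sum().backward()
                influence = np.abs(xt.grad).sum(axis=(0, 1))
                assert np.all(influence > 0), f"pixel ({pi},{pj}) lacks full influence"

    def test_every_parameter_receives_gradient(self):
        block = TPABlock(AttentionConfig(8, 2, 2), rng=np.random.default_rng(14))
        x = Tensor(rng.normal(size=(2, 8, 4, 4)), requires_grad=True)
        block(x).sum().backward()
        for name, p in block.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), f"dead parameter {name}"
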