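"""Block contracts and end-to-end shape/gradient tests for the backbone."""

import numpy as np
import pytest

from vesselseg.backbone import (
    DecoderBlock,
    DSBlock,
    FEBlock,
    ModelConfig,
    MTPAUnet,
    MultilayerPool,
    SCIFuse,
    SegmentationResult,
    count_parameters,
    desk_config,
    load_checkpoint,
    save_checkpoint,
)
from vesselseg.metrics import dice_loss_tensor
from vesselseg.nn import Conv2d
from vesselseg.nn.tensor import Tensor
from vesselseg.preprocessing import build_pyramid

rng = np.random.default_rng(21)


def _pyramids(n=2, seed=0):
    r = np.random.default_rng(seed)
    return [build_pyramid(r.random((64, 64)), (0, 0)) for _ in range(n)]


class TestFEBlock:
    def test_shape_and_channel_contract(self):
        fe = FEBlock(8, 12, rng=np.random.default_rng(0))
        out = fe(Tensor(rng.normal(size=(2, 8, 10, 10))))
        assert out.shape == (2, 12, 10, 10)

    def test_parameter_count_matches_hand_tally(self):
        # in=32, out=32, reduce=16: 1x1 reduce + 3x3 conv + 3x3 transposed
        # conv + 1x1 bottleneck + batch norm (identity residual, no proj)
        fe = FEBlock(32, 32, reduce=16)
        tally = (
            (32 * 16 + 16)  # 1x1 reduce
            + (16 * 16 * 9 + 16)  # 3x3 conv
            + (16 * 16 * 9 + 16)  # 3x3 transposed conv
            + (2 * 16 * 32 + 32)  # 1x1 bottleneck on the fused 32 channels
            + 2 * 32  # batch norm gain/offset
        )
        assert fe.num_parameters() == tally == 6288


class TestDSBlock:
    def test_halves_spatial_side(self):
        ds = DSBlock(4, rng=np.random.default_rng(1))
        assert ds(Tensor(rng.normal(size=(1, 4, 32, 32)))).shape == (1, 4, 16, 16)

    def test_four_applications_reach_four(self):
        ds = DSBlock(2, rng=np.random.default_rng(2))
        x = Tensor(rng.normal(size=(1, 2, 64, 64)))
        for _ in range(4):
            x = ds(x)
        assert x.shape == (1, 2, 4, 4)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            DSBlock(2)(Tensor(np.zeros((1, 2, 5, 6))))

    def test_frozen_identity_reduces_to_mean_pooling(self):
        ds = DSBlock(1)
        ds.eval()  # running stats (0, 1) -> affine identity
        ds.norms[0].eps = 0.0
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0
        ds.conv.weight.data = w
        ds.conv.bias.data = np.zeros(1)
        x = np.abs(rng.normal(size=(1, 1, 8, 8)))  # positive: ReLU transparent
        out = ds(Tensor(x)).data
        ref = x.reshape(1, 1, 4, 2, 4, 2).mean(axis=(3, 5))
        assert np.allclose(out, ref, atol=1e-10)

    def test_triple_norm_mode_has_three_norms(self):
        assert len(DSBlock(2, triple_norm=True).norms) == 3


class TestMultilayerPool:
    def test_shape_preserved(self):
        mp = MultilayerPool(8, (1, 2, 3, 6), rng=np.random.default_rng(3))
        assert mp(Tensor(rng.normal(size=(1, 8, 8, 8)))).shape == (1, 8, 8, 8)

    def test_constant_input_gives_constant_output(self):
        mp = MultilayerPool(4, (1, 2), rng=np.random.default_rng(4))
        out = mp(Tensor(np.full((1, 4, 6, 6), 1.5))).data
        for ch in range(4):
            assert np.allclose(out[0, ch], out[0, ch, 0, 0])

    def test_branch_pooling_matches_block_means(self):
        mp = MultilayerPool(2, (1, 2), rng=np.random.default_rng(5))
        # identity-select channel 0 in both branch convs
        for conv in mp.branches:
            conv.weight.data = np.array([[[[1.0]], [[0.0]]]])
            conv.bias.data = np.zeros(1)
        x = rng.normal(size=(1, 2, 4, 4))
        from vesselseg.nn.functional import adaptive_avg_pool2d

        b1 = mp.branches[0](adaptive_avg_pool2d(Tensor(x), (1, 1))).data
        b2 = mp.branches[1](adaptive_avg_pool2d(Tensor(x), (2, 2))).data
        assert np.allclose(b1[0, 0, 0, 0], x[0, 0].mean())
        assert np.allclose(b2[0, 0], x[0, 0].reshape(2, 2, 2, 2).mean(axis=(1, 3)))

    def test_scale_exceeding_side_rejected(self):
        mp = MultilayerPool(2, (1, 6))
        with pytest.raises(ValueError, match="scale"):
            mp(Tensor(np.zeros((1, 2, 4, 4))))


class TestSCIFuse:
    def _outputs(self):
        chans = (4, 8, 16, 32)
        sizes = (32, 16, 8, 4)
        return [Tensor(rng.normal(size=(1, c, s, s))) for c, s in zip(chans, sizes)], chans

    def test_output_matches_deepest_shape_and_width(self):
        outs, chans = self._outputs()
        sci = SCIFuse(chans, rng=np.random.default_rng(6))
        fused = sci(outs)
        assert fused.shape == (1, 32, 4, 4)

    def test_shallow_information_reaches_bottom(self):
        outs, chans = self._outputs()
        sci = SCIFuse(chans, rng=np.random.default_rng(7))
        full = sci(outs).data
        zeroed = [Tensor(np.zeros_like(t.data)) for t in outs[:3]] + [outs[3]]
        assert not np.allclose(full, sci(zeroed).data)

    def test_wrong_arity_rejected(self):
        sci = SCIFuse((4, 8, 16, 32))
        with pytest.raises(ValueError):
            sci([Tensor(np.zeros((1, 4, 8, 8)))])


class TestDecoderBlock:
    def test_output_matches_skip_size(self):
        dec = DecoderBlock(8, 4, 6, rng=np.random.default_rng(8))
        out = dec(Tensor(rng.normal(size=(1, 8, 4, 4))), Tensor(rng.normal(size=(1, 4, 8, 8))))
        assert out.shape == (1, 6, 8, 8)

    def test_zero_skip_leaves_upsampled_path(self):
        dec = DecoderBlock(4, 4, 4, rng=np.random.default_rng(9))
        x = Tensor(rng.normal(size=(1, 4, 4, 4)))
        zskip = Tensor(np.zeros((1, 4, 8, 8)))
        from vesselseg.nn.functional import interpolate_bilinear

        expected = dec.refine(dec.align(interpolate_bilinear(x, (8, 8)))).data
        assert np.allclose(dec(x, zskip).data, expected, atol=1e-10)

    def test_size_mismatch_rejected(self):
        dec = DecoderBlock(4, 4, 4)
        with pytest.raises(ValueError):
            dec(Tensor(np.zeros((1, 4, 4, 4))), Tensor(np.zeros((1, 4, 9, 9))))


class TestMTPAUnet:
    def test_end_to_end_probability_map(self):
        model = MTPAUnet(desk_config(seed=0))
        out = model.forward_pyramids(_pyramids(2))
        assert out.shape == (2, 1, 64, 64)
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_eval_mode_is_bit_stable(self):
        model = MTPAUnet(desk_config(seed=1))
        pyrs = _pyramids(1, seed=5)
        a = model.predict_pyramids(pyrs)
        b = model.predict_pyramids(pyrs)
        assert np.array_equal(a, b)

    def test_gradient_coverage_no_dead_parameters(self):
        model = MTPAUnet(desk_config(seed=2))
        pyrs = _pyramids(2, seed=6)
        probs = model.forward_pyramids(pyrs)
        target = Tensor((np.random.default_rng(0).random((2, 1, 64, 64)) > 0.9).astype(float))
        loss = dice_loss_tensor(probs, target)
        model.zero_grad()
        loss.backward()
        dead = [n for n, p in model.named_parameters() if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_pyramid_mismatch_rejected(self):
        model = MTPAUnet(desk_config())
        levels = [Tensor(np.zeros((1, 1, 32, 32)))] * 4
        with pytest.raises(ValueError, match="pyramid"):
            model.forward(levels)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(channels=(32, 64, 100, 256)).validate()
        with pytest.raises(ValueError):
            ModelConfig(input_sizes=(64, 32, 16, 4)).validate()


class TestParameterCount:
    def test_lone_pointwise_conv(self):
        conv = Conv2d(2, 3, 1, bias=True)
        assert conv.num_parameters() == 9  # 2*3 + 3

    def test_count_independent_of_input_size(self):
        a = count_parameters(desk_config())
        b = count_parameters(
            ModelConfig(
                channels=(8, 16, 32, 64),
                decoder_channels=(64, 32, 16, 8),
                input_sizes=(128, 64, 32, 16),
            )
        )
        assert a == b


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        model = MTPAUnet(desk_config(seed=3))
        pyrs = _pyramids(1, seed=7)
        before = model.predict_pyramids(pyrs)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model)
        restored = load_checkpoint(path)
        assert restored.cfg == model.cfg
        assert np.array_equal(restored.predict_pyramids(pyrs), before)


class TestSegmentationResult:
    def test_mask_is_thresholded_probability(self):
        p = rng.random((8, 8))
        res = SegmentationResult(prob_map=p, threshold=0.4)
        assert np.array_equal(res.bin_mask, (p >= 0.4).astype(np.uint8))

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            SegmentationResult(prob_map=np.zeros((2, 2)), threshold=1.5)
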