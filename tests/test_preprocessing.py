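"""Enhancement chain and patch machinery tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import uniform_filter

from vesselseg.preprocessing import (
    PreprocessConfig,
    build_pyramid,
    clahe,
    extract_patches,
    fuse_channels,
    gamma_correct,
    grid_origins,
    normalize,
    preprocess,
    stitch,
)


class TestFuseChannels:
    def test_gray_pixel_is_fixed_point(self):
        img = np.full((2, 2, 3), 100.0)
        assert np.allclose(fuse_channels(img), 100.0)

    def test_pure_green_default_weights(self):
        img = np.zeros((1, 1, 3))
        img[0, 0] = (0, 255, 0)
        assert np.allclose(fuse_channels(img), 0.587 * 255)  # 149.685

    def test_red_projection(self):
        img = np.arange(12, dtype=float).reshape(2, 2, 3)
        assert np.array_equal(fuse_channels(img, (1, 0, 0)), img[..., 0])

    def test_rejects_bad_weights(self):
        with pytest.raises(ValueError, match="sum to 1"):
            fuse_channels(np.zeros((2, 2, 3)), (0.5, 0.4, 0.2))


class TestNormalize:
    def test_output_spans_unit_interval(self):
        out = normalize(np.random.default_rng(0).normal(size=(16, 16)))
        assert out.min() == 0.0 and out.max() == 1.0

    @given(a=st.floats(0.1, 10), b=st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.random.default_rng(1).normal(size=(8, 8))
        assert np.allclose(normalize(a * x + b), normalize(x), atol=1e-10)

    def test_two_pixel_image(self):
        assert np.allclose(normalize(np.array([10.0, 20.0])), [0.0, 1.0])

    def test_constant_image_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize(np.full((4, 4), 3.0))
        assert np.all(out == 0)


class TestClahe:
    def test_constant_image_stays_near_constant(self):
        out = clahe(np.full((64, 64), 0.5))
        assert out.std() < 1e-6

    def test_output_stays_in_declared_range(self, enhanced):
        assert enhanced.min() >= 0.0 and enhanced.max() <= 1.0

    def test_increases_local_contrast(self, synth_sample):
        g = normalize(fuse_channels(synth_sample.image))
        out = clahe(g)
        fov = synth_sample.fov_mask.astype(bool)

        def local_sd(img):
            m = uniform_filter(img, 7)
            m2 = uniform_filter(img * img, 7)
            return np.sqrt(np.clip(m2 - m * m, 0, None))[fov].mean()

        assert local_sd(out) > local_sd(g)

    def test_rejects_nonpositive_clip(self):
        with pytest.raises(ValueError):
            clahe(np.zeros((8, 8)), clip=0.0)


class TestGamma:
    def test_identity_at_one(self):
        x = np.random.default_rng(2).random((8, 8))
        assert np.array_equal(gamma_correct(x, 1.0), x)

    def test_closed_form(self):
        assert gamma_correct(np.array([0.25]), 2.0)[0] == pytest.approx(0.0625)

    @given(g=st.floats(0.2, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_monotone(self, g):
        x = np.sort(np.random.default_rng(3).random(32))
        out = gamma_correct(x, g)
        assert np.all(np.diff(out) >= 0)

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError):
            gamma_correct(np.zeros(3), 0.0)


class TestPreprocess:
    def test_equals_manual_composition(self, synth_sample):
        cfg = PreprocessConfig()
        manual = gamma_correct(
            clahe(
                normalize(fuse_channels(synth_sample.image, cfg.fusion_weights)),
                cfg.clahe_clip,
                cfg.clahe_tiles,
            ),
            cfg.gamma,
        )
        assert np.array_equal(preprocess(synth_sample, cfg), manual)

    def test_deterministic(self, synth_sample):
        assert np.array_equal(preprocess(synth_sample), preprocess(synth_sample))

    def test_enhances_vessel_background_contrast(self, synth_sample, enhanced):
        before = normalize(fuse_channels(synth_sample.image))
        vessel = synth_sample.vessel_mask.astype(bool)
        bg = synth_sample.fov_mask.astype(bool) & ~vessel
        contrast_before = before[bg].mean() - before[vessel].mean()
        contrast_after = enhanced[bg].mean() - enhanced[vessel].mean()
        assert contrast_after > contrast_before


class TestPatches:
    def test_grid_origins_cover_128(self):
        origins = grid_origins((128, 128), stride=64)
        assert sorted(origins) == [(0, 0), (0, 64), (64, 0), (64, 64)]

    def test_grid_covers_every_pixel(self):
        origins = grid_origins((130, 97), stride=32)
        cov = np.zeros((130, 97), int)
        for r, c in origins:
            cov[r : r + 64, c : c + 64] += 1
        assert cov.min() >= 1

    def test_random_mode_is_seeded(self, enhanced, synth_sample):
        kw = dict(n=12, mode="random", seed=5)
        a = extract_patches(enhanced, synth_sample.vessel_mask, synth_sample.fov_mask, **kw)
        b = extract_patches(enhanced, synth_sample.vessel_mask, synth_sample.fov_mask, **kw)
        assert [p.origin for p, _ in a] == [p.origin for p, _ in b]

    def test_random_centers_inside_fov(self, enhanced, synth_sample):
        pairs = extract_patches(
            enhanced, synth_sample.vessel_mask, synth_sample.fov_mask, n=30, seed=2
        )
        for pyr, _ in pairs:
            r, c = pyr.origin
            assert synth_sample.fov_mask[r + 32, c + 32] == 1

    def test_pyramid_levels_are_mean_pooled(self, enhanced):
        (pyr, _), = extract_patches(enhanced, n=1, mode="random", seed=9)
        l64 = pyr.level64
        ref32 = l64.reshape(32, 2, 32, 2).mean(axis=(1, 3))
        assert np.allclose(pyr.level32, ref32)
        assert np.allclose(pyr.level16, ref32.reshape(16, 2, 16, 2).mean(axis=(1, 3)))
        assert pyr.level8.shape == (8, 8)

    def test_labels_cropped_at_origin(self, enhanced, synth_sample):
        pairs = extract_patches(
            enhanced, synth_sample.vessel_mask, synth_sample.fov_mask, n=3, seed=4
        )
        for pyr, lab in pairs:
            r, c = pyr.origin
            assert np.array_equal(lab, synth_sample.vessel_mask[r : r + 64, c : c + 64])

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((32, 32)))


class TestStitch:
    def test_single_full_patch_identity(self):
        p = np.random.default_rng(0).random((64, 64))
        assert np.array_equal(stitch([p], [(0, 0)], (64, 64)), p)

    def test_overlap_averages(self):
        a = np.full((64, 64), 0.2)
        b = np.full((64, 64), 0.6)
        out = stitch([a, b], [(0, 0), (0, 32)], (64, 96))
        assert np.allclose(out[:, 32:64], 0.4)
        assert np.allclose(out[:, :32], 0.2)
        assert np.allclose(out[:, 64:], 0.6)

    def test_identical_overlap_unchanged(self):
        p = np.random.default_rng(1).random((64, 64))
        out = stitch([p, p], [(0, 0), (0, 0)], (64, 64))
        assert np.allclose(out, p)

    def test_uncovered_pixels_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            stitch([np.zeros((64, 64))], [(0, 0)], (64, 96))

    def test_grid_roundtrip_on_constant_map(self):
        const = np.full((128, 128), 0.37)
        pairs = extract_patches(const, mode="grid", stride=32)
        patches = [p.level64 for p, _ in pairs]
        origins = [p.origin for p, _ in pairs]
        out = stitch(patches, origins, (128, 128))
        assert np.allclose(out, 0.37)
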