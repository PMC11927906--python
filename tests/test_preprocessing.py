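"""Channel statistics, standardization, and the augmentation operators."""

import numpy as np
import pytest

from platescreen import (
    AugmentationPolicy, ChannelStats, CropImage, augment_dataset,
    compute_channel_stats, denormalize, hflip, multiplicative_noise,
    normalize, rgb_shift, rot90, solarize, vflip,
)
from platescreen.preprocessing import AUGMENT_OPS, apply_op


def _crop(px, **kw):
    kw.setdefault("plate_id", "P")
    kw.setdefault("well_id", "W")
    kw.setdefault("crop_index", 0)
    return CropImage(pixels=px, **kw)


class TestChannelStats:
    def test_constant_input_is_degenerate(self):
        c = _crop(np.full((8, 8, 3), 255, dtype=np.uint8))
        with pytest.raises(ValueError):
            compute_channel_stats([c])

    def test_half_black_half_white_means_half(self):
        a = _crop(np.zeros((8, 8, 3), dtype=np.uint8))
        b = _crop(np.full((8, 8, 3), 255, dtype=np.uint8))
        s = compute_channel_stats([a, b])
        assert s.mu == pytest.approx((0.5, 0.5, 0.5))
        assert s.n_pixels == 128

    def test_pooled_halves_equal_union(self):
        rng = np.random.default_rng(0)
        crops = [_crop(rng.integers(0, 256, (8, 8, 3)).astype(np.uint8))
                 for _ in range(6)]
        su = compute_channel_stats(crops)
        # pooling identity on counts/sums: recompute from the two halves' sums
        s1 = compute_channel_stats(crops[:3])
        s2 = compute_channel_stats(crops[3:])
        n1, n2 = s1.n_pixels, s2.n_pixels
        mu = (np.array(s1.mu) * n1 + np.array(s2.mu) * n2) / (n1 + n2)
        ex2 = ((np.array(s1.sigma) ** 2 + np.array(s1.mu) ** 2) * n1
               + (np.array(s2.sigma) ** 2 + np.array(s2.mu) ** 2) * n2) / (n1 + n2)
        assert np.allclose(su.mu, mu)
        assert np.allclose(np.array(su.sigma) ** 2, ex2 - mu ** 2)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            compute_channel_stats([])


class TestNormalize:
    def test_pixel_at_mean_centers_to_zero(self):
        s = ChannelStats(mu=(0.4, 0.4, 0.4), sigma=(0.2, 0.2, 0.2), n_pixels=1)
        c = _crop(np.full((4, 4, 3), 0.4 * 255))
        assert np.allclose(normalize(c, s).pixels, 0.0)

    def test_hand_computed_value(self):
        # p = 255, mu = 0.5, sigma = 0.25 -> (255 - 127.5) / 63.75 = 2.0
        s = ChannelStats(mu=(0.5, 0.5, 0.5), sigma=(0.25, 0.25, 0.25), n_pixels=1)
        c = _crop(np.full((2, 2, 3), 255, dtype=np.uint8))
        assert np.allclose(normalize(c, s).pixels, 2.0)

    def test_training_set_standardizes_to_unit_moments(self):
        rng = np.random.default_rng(1)
        crops = [_crop(rng.integers(0, 256, (16, 16, 3)).astype(np.uint8))
                 for _ in range(5)]
        s = compute_channel_stats(crops)
        normed = np.concatenate(
            [normalize(c, s).pixels.reshape(-1, 3) for c in crops])
        assert np.allclose(normed.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(normed.std(axis=0), 1.0, atol=1e-6)

    def test_denormalize_round_trip(self):
        s = ChannelStats(mu=(0.3, 0.5, 0.7), sigma=(0.1, 0.2, 0.3), n_pixels=1)
        rng = np.random.default_rng(2)
        c = _crop(rng.integers(0, 256, (8, 8, 3)).astype(np.uint8))
        back = denormalize(normalize(c, s), s)
        assert np.abs(back.pixels - c.pixels).max() < 1e-9

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ChannelStats(mu=(0.5, 0.5, 0.5), sigma=(0.2, 0.0, 0.2), n_pixels=1)


class TestSolarize:
    def test_below_threshold_is_identity(self):
        img = np.linspace(0, 0.9, 27).reshape(3, 3, 3)
        assert (solarize(img, 0.95) == img).all()

    def test_bright_pixels_invert(self):
        # the bright part turns dark: 0.99 -> 1 - 0.99 = 0.01
        img = np.array([[[0.99, 0.5, 0.96]]])
        out = solarize(img, 0.95)
        assert out[0, 0, 0] == pytest.approx(0.01)
        assert out[0, 0, 1] == pytest.approx(0.5)
        assert out[0, 0, 2] == pytest.approx(0.04)

    def test_literal_mask_zeroes_dim_pixels(self):
        # the raw indicator product keeps only supra-threshold values
        img = np.array([[[0.99, 0.5, 0.96]]])
        out = solarize(img, 0.95, mode="literal_mask")
        assert out[0, 0, 0] == pytest.approx(0.99)
        assert out[0, 0, 1] == 0.0
        assert out[0, 0, 2] == pytest.approx(0.96)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            solarize(np.zeros((2, 2, 3)), threshold=1.5)


class TestMultiplicativeNoise:
    def test_zero_noise_is_identity(self):
        img = np.random.default_rng(0).random((4, 4, 3))
        assert (multiplicative_noise(img, (0.0, 0.0), seed=1) == img).all()

    def test_degenerate_range_scales_exactly(self):
        # p = 0.5 with u fixed at 0.1 -> 0.55
        img = np.full((2, 2, 3), 0.5)
        assert np.allclose(multiplicative_noise(img, (0.1, 0.1), seed=0), 0.55)

    def test_mean_matches_uniform_expectation(self):
        img = np.full((50, 50, 3), 0.4)
        outs = [multiplicative_noise(img, (-0.2, 0.1), seed=s).mean()
                for s in range(20)]
        # E[p(1+u)] = 0.4 * (1 + (-0.2 + 0.1)/2) = 0.38
        assert np.mean(outs) == pytest.approx(0.38, abs=0.002)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            multiplicative_noise(np.zeros((2, 2, 3)), (0.3, 0.1))


class TestGeometricOps:
    def test_flips_are_involutions(self):
        img = np.random.default_rng(3).random((6, 8, 3))
        assert (hflip(hflip(img)) == img).all()
        assert (vflip(vflip(img)) == img).all()

    def test_rot90_four_times_is_identity(self):
        img = np.random.default_rng(4).random((8, 8, 3))
        out = img
        for _ in range(4):
            out = rot90(out)
        assert (out == img).all()

    @pytest.mark.parametrize("op", ["hflip", "vflip", "rot90"])
    def test_geometric_ops_preserve_pixel_multiset(self, op):
        img = np.random.default_rng(5).random((8, 8, 3))
        out = apply_op(op, img, np.random.default_rng(0))
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_rgb_shift_is_additive(self):
        out = rgb_shift(np.zeros((4, 4, 3)), (0.1, 0.0, 0.0))
        assert np.allclose(out[:, :, 0], 0.1)
        assert out[:, :, 1:].max() == 0.0

    def test_rgb_shift_range_checked(self):
        with pytest.raises(ValueError):
            rgb_shift(np.zeros((2, 2, 3)), (1.5, 0, 0))


class TestAugmentDataset:
    def _crops(self, n):
        rng = np.random.default_rng(6)
        return [_crop(rng.integers(0, 200, (16, 16, 3)).astype(np.uint8),
                      crop_index=i % 15) for i in range(n)]

    def test_ten_percent_fraction_adds_ten_copies(self):
        out = augment_dataset(self._crops(100), AugmentationPolicy(fraction=0.1, rng_seed=1))
        assert len(out) == 110
        assert sum(c.augmented for c in out) == 10
        assert all(not c.augmented for c in out[:100])

    def test_zero_fraction_is_noop(self):
        crops = self._crops(10)
        assert augment_dataset(crops, AugmentationPolicy(fraction=0.0)) == crops

    def test_same_seed_reproduces_selection_and_ops(self):
        crops = self._crops(40)
        p = AugmentationPolicy(fraction=0.25, rng_seed=9)
        a = augment_dataset(crops, p)
        b = augment_dataset(crops, p)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            assert (x.pixels == y.pixels).all()

    def test_empty_op_set_with_positive_fraction_rejected(self):
        with pytest.raises(ValueError):
            AugmentationPolicy(fraction=0.1, ops=())

    @pytest.mark.parametrize("op", sorted(AUGMENT_OPS))
    def test_every_op_keeps_range_and_shape(self, op):
        img = np.random.default_rng(7).random((32, 32, 3))
        out = apply_op(op, img, np.random.default_rng(1))
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0 + 1e-12
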