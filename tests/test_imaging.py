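"""Color decomposition, histograms and Otsu thresholding."""

import colorsys
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage.filters import threshold_otsu

from selfieplaque import (
    apply_band_threshold,
    channel_histogram,
    hsb_to_rgb,
    otsu_threshold,
    rgb_to_hsb,
)


def colorsys_hsb(r, g, b):
    """Independent byte-scaled HSB oracle via the stdlib colorsys module."""
    h, s, v = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)
    return round(h * 255), round(s * 255), round(v * 255)


def brute_force_otsu(hist):
    """Exact-arithmetic exhaustive scan over all 256 split levels.

    Between-class variance at split t is (S0*w1 - S1*w0)^2 / (w0*w1) with
    integer sums, compared as exact Fractions; smallest maximizing t wins.
    """
    hist = [int(c) for c in hist]
    levels = list(range(256))
    best_t, best_v = None, Fraction(-1)
    for t in range(256):
        w0 = sum(hist[: t + 1])
        w1 = sum(hist[t + 1 :])
        if w0 == 0 or w1 == 0:
            continue
        s0 = sum(l * c for l, c in zip(levels[: t + 1], hist[: t + 1]))
        s1 = sum(l * c for l, c in zip(levels[t + 1 :], hist[t + 1 :]))
        v = Fraction((s0 * w1 - s1 * w0) ** 2, w0 * w1)
        if v > best_v:
            best_t, best_v = t, v
    return best_t


class TestRgbToHsb:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 0, 0), (0, 255, 255)),     # pure red
            ((128, 128, 128), (0, 0, 128)),   # gray: zero saturation
            ((64, 128, 192), (149, 170, 192)),
            ((0, 0, 0), (0, 0, 0)),
            ((0, 255, 0), (85, 255, 255)),    # green: 120 deg -> 85/255
        ],
    )
    def test_byte_scaled_decomposition(self, rgb, expected):
        pixel = np.array([[rgb]], dtype=np.uint8)
        assert tuple(rgb_to_hsb(pixel)[0, 0]) == expected
        assert colorsys_hsb(*rgb) == expected

    def test_matches_colorsys_oracle_on_random_pixels(self, rng):
        rgb = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        hsb = rgb_to_hsb(rgb)
        for i in range(16):
            for j in range(16):
                assert tuple(hsb[i, j]) == colorsys_hsb(*rgb[i, j])

    def test_round_trip_bounded_by_hue_quantization(self, rng):
        # byte-scaled hue has 255 levels over 360 deg; a half-level hue
        # error moves a channel by at most 255 * (360/255/2) / 60 = 1.5
        # at full saturation, plus half-level S and V rounding -> <= 4
        rgb = rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8)
        back = hsb_to_rgb(rgb_to_hsb(rgb))
        assert np.max(np.abs(back.astype(int) - rgb.astype(int))) <= 4

    def test_round_trip_exact_on_gray_and_primaries(self):
        pixels = np.array(
            [[(0, 0, 0), (255, 255, 255), (128, 128, 128),
              (255, 0, 0), (0, 255, 0), (0, 0, 255)]], dtype=np.uint8
        )
        np.testing.assert_array_equal(hsb_to_rgb(rgb_to_hsb(pixels)), pixels)

    def test_gray_pixels_have_zero_saturation(self, rng):
        g = rng.integers(0, 256, size=(5, 5, 1), dtype=np.uint8)
        hsb = rgb_to_hsb(np.repeat(g, 3, axis=2))
        assert np.all(hsb[:, :, 1] == 0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty|shape"):
            rgb_to_hsb(np.zeros((0, 4, 3), dtype=np.uint8))


class TestChannelHistogram:
    def test_uniform_raster(self):
        h = channel_histogram(np.full((2, 2), 7, dtype=np.uint8))
        assert h[7] == 4 and h.sum() == 4

    def test_all_false_mask_counts_nothing(self):
        ch = np.arange(4, dtype=np.uint8).reshape(2, 2)
        h = channel_histogram(ch, np.zeros((2, 2), dtype=bool))
        assert h.sum() == 0

    def test_corner_mask_enumeration(self):
        ch = np.arange(9, dtype=np.uint8).reshape(3, 3)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[0, 2] = mask[2, 0] = mask[2, 2] = True
        h = channel_histogram(ch, mask)
        assert all(h[v] == 1 for v in (0, 2, 6, 8)) and h.sum() == 4

    def test_total_equals_masked_pixel_count(self, rng):
        ch = rng.integers(0, 256, size=(20, 30), dtype=np.uint8)
        mask = rng.random((20, 30)) < 0.4
        assert channel_histogram(ch, mask).sum() == mask.sum()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            channel_histogram(np.zeros((2, 2), np.uint8), np.ones((3, 3), bool))


class TestOtsu:
    def test_two_point_separation_smallest_tie(self):
        h = np.zeros(256, dtype=int)
        h[10] = h[200] = 50
        assert otsu_threshold(h) == 10  # any t in [10,199] ties; smallest wins

    def test_single_level_degenerate(self):
        h = np.zeros(256, dtype=int)
        h[50] = 9
        assert otsu_threshold(h) == 50

    def test_three_mass_histogram_matches_exhaustive_scan(self):
        h = np.zeros(256, dtype=int)
        h[20], h[30], h[220] = 30, 30, 40
        assert otsu_threshold(h) == brute_force_otsu(h)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            otsu_threshold(np.zeros(256, dtype=int))

    @settings(max_examples=120, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_brute_force_on_random_histograms(self, seed):
        h = np.random.default_rng(seed).integers(0, 25, size=256)
        if h.sum() == 0:
            h[0] = 1
        assert otsu_threshold(h) == brute_force_otsu(h)

    def test_agrees_with_skimage_on_random_histograms(self, rng):
        for _ in range(25):
            h = rng.integers(0, 20, size=256)
            assert otsu_threshold(h) == threshold_otsu(hist=(h, np.arange(256)))


class TestBandThreshold:
    def test_full_band_selects_everything(self, rng):
        ch = rng.integers(0, 256, size=(8, 8), dtype=np.uint8)
        assert apply_band_threshold(ch, 0, 255).all()

    def test_absent_value_selects_nothing(self):
        ch = np.array([[5, 20, 30]], dtype=np.uint8)
        assert not apply_band_threshold(ch, 10, 10).any()

    def test_closed_band_boundaries(self):
        ch = np.array([[99, 100, 200]], dtype=np.uint8)
        np.testing.assert_array_equal(
            apply_band_threshold(ch, 100, 200)[0], [False, True, True]
        )

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            apply_band_threshold(np.zeros((2, 2), np.uint8), 200, 100)

    def test_count_monotone_in_band_width(self, rng):
        ch = rng.integers(0, 256, size=(30, 30), dtype=np.uint8)
        counts = [
            apply_band_threshold(ch, 128 - w, 128 + w).sum() for w in range(0, 128, 7)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
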