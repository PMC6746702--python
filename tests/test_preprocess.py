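"""Contrast enhancement, area masks, column zeroing and flip augmentation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chorioseg import (
    boundaries_to_area_mask,
    area_mask_to_boundaries,
    contrast_enhance,
    generate_boundaries,
    render_bscan,
    zero_missing_columns,
)
from chorioseg.core import BScan, BoundarySet
from chorioseg.preprocess import random_horizontal_flip, validate_area_mask


class TestContrastEnhance:
    def test_single_pixel_column_near_half(self):
        scan = BScan(np.array([[100.0]]))
        out = contrast_enhance(scan, exponent=2, floor=1e-8, rescale=False)
        assert out.pixels[0, 0] == pytest.approx(0.5, abs=1e-6)

    def test_two_pixel_column_closed_form(self):
        a, b = 3.0, 5.0
        eps = 1e-8
        scan = BScan(np.array([[a], [b]]))
        out = contrast_enhance(scan, exponent=1, floor=eps, rescale=False)
        np.testing.assert_allclose(
            out.pixels[:, 0], [a / (2 * (a + b) + eps), b / (2 * b + eps)])

    def test_all_zero_column_stays_zero(self):
        scan = BScan(np.array([[0.0, 10.0], [0.0, 20.0]]))
        out = contrast_enhance(scan)
        assert np.all(out.pixels[:, 0] == 0)

    def test_output_finite_nonnegative_and_rescaled(self, noisy_params):
        scan = render_bscan(noisy_params, generate_boundaries(noisy_params))
        out = contrast_enhance(scan)
        assert np.isfinite(out.pixels).all()
        assert out.pixels.min() >= 0
        assert out.pixels.max() == pytest.approx(255.0)

    def test_enhancement_boosts_choroid_sclera_contrast(self, clean_params):
        """On a noise-free phantom the choroid/sclera intensity ratio
        (matched-thickness bands at the CSI) increases after attenuation
        compensation: the depth decay suppressing the choroid is removed."""
        params = dataclasses.replace(clean_params, height=128,
                                     curvature_amplitude=0.0,
                                     attenuation_rate=0.004)
        bounds = generate_boundaries(params)
        scan = render_bscan(params, bounds)
        rpe, csi = int(params.mean_depths[1]), int(params.mean_depths[2])
        band = csi - rpe
        enhanced = contrast_enhance(scan)

        def ratio(img):
            return img[rpe:csi].mean() / img[csi:csi + band].mean()

        assert ratio(enhanced.pixels) > ratio(scan.pixels)


class TestAreaMask:
    def test_constant_boundaries_label_counts(self):
        bs = BoundarySet(np.full(5, 10.0), np.full(5, 20.0), np.full(5, 30.0))
        mask = boundaries_to_area_mask(bs, height=40)
        counts = np.bincount(mask[:, 0], minlength=4)
        np.testing.assert_array_equal(counts, [10, 10, 10, 10])

    def test_missing_boundary_column_is_all_vitreous(self):
        bs = BoundarySet(np.array([10.0, 10.0]), np.array([20.0, 20.0]),
                         np.array([30.0, np.nan]))
        mask = boundaries_to_area_mask(bs, height=40)
        assert set(np.unique(mask[:, 1])) == {0}
        assert set(np.unique(mask[:, 0])) == {0, 1, 2, 3}

    def test_round_trip_recovers_integer_boundaries(self, clean_scan):
        _, bounds = clean_scan
        mask = boundaries_to_area_mask(bounds, height=64)
        back = area_mask_to_boundaries(mask)
        from chorioseg.core import round_half_up
        for name in ("ilm", "rpe", "csi"):
            np.testing.assert_array_equal(back[name],
                                          round_half_up(bounds[name]))

    def test_half_up_rounding(self):
        bs = BoundarySet(np.array([9.5]), np.array([20.49]), np.array([30.5]))
        mask = boundaries_to_area_mask(bs, height=40)
        col = mask[:, 0]
        assert col[9] == 0 and col[10] == 1    # 9.5 rounds up to 10
        assert col[19] == 1 and col[20] == 2   # 20.49 rounds down to 20
        assert col[30] == 2 and col[31] == 3   # 30.5 rounds up to 31

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mask_monotone_invariant(self, seed):
        from chorioseg import PhantomParams
        params = PhantomParams(width=32, height=48,
                               mean_depths=(12.0, 22.0, 34.0),
                               curvature_amplitude=8.0,
                               curvature_smoothness=10.0,
                               missing_margin=4, seed=seed)
        mask = boundaries_to_area_mask(generate_boundaries(params), 48)
        validate_area_mask(mask)  # raises on violation


class TestZeroMissingColumns:
    def test_identity_when_nothing_missing(self, clean_scan):
        scan, bounds = clean_scan
        np.testing.assert_array_equal(
            zero_missing_columns(scan, bounds).pixels, scan.pixels)

    def test_exact_columns_zeroed_and_mass_bookkeeping(self, clean_scan):
        scan, bounds = clean_scan
        bounds = bounds.copy()
        cols = [0, 3, 10, 50, 95]
        bounds.csi[cols] = np.nan
        out = zero_missing_columns(scan, bounds)
        assert (out.pixels[:, cols] == 0).all()
        removed = scan.pixels[:, cols].sum()
        assert scan.pixels.sum() - out.pixels.sum() == pytest.approx(removed)
        untouched = np.setdiff1d(np.arange(scan.width), cols)
        np.testing.assert_array_equal(out.pixels[:, untouched],
                                      scan.pixels[:, untouched])


class TestRandomHorizontalFlip:
    def test_forced_flip_reverses_columns_consistently(self):
        rng = np.random.default_rng(0)
        img = np.arange(12.0).reshape(3, 4)
        mask = np.arange(12).reshape(3, 4) % 4
        flipped_img, flipped_mask, did = random_horizontal_flip(
            img, mask, rng, probability=1.0)
        assert did
        np.testing.assert_array_equal(flipped_img, img[:, ::-1])
        np.testing.assert_array_equal(flipped_mask, mask[:, ::-1])

    def test_double_forced_flip_is_identity(self):
        rng = np.random.default_rng(0)
        img = np.random.default_rng(1).random((5, 7))
        mask = np.zeros((5, 7), dtype=int)
        once = random_horizontal_flip(img, mask, rng, probability=1.0)
        twice = random_horizontal_flip(once[0], once[1], rng, probability=1.0)
        np.testing.assert_array_equal(twice[0], img)

    def test_flip_frequency_binomial(self):
        rng = np.random.default_rng(123)
        img = np.zeros((2, 2))
        mask = np.zeros((2, 2), dtype=int)
        flips = sum(random_horizontal_flip(img, mask, rng)[2]
                    for _ in range(10_000))
        assert abs(flips / 10_000 - 0.5) < 0.02

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="shape"):
            random_horizontal_flip(np.zeros((3, 4)), np.zeros((3, 5)), rng)

    def test_flip_preserves_mask_monotonicity(self, clean_scan):
        scan, bounds = clean_scan
        mask = boundaries_to_area_mask(bounds, scan.height)
        rng = np.random.default_rng(5)
        _, flipped_mask, _ = random_horizontal_flip(scan.pixels, mask, rng,
                                                    probability=1.0)
        validate_area_mask(flipped_mask)
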