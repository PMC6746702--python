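"""Phantom generator: ordering, determinism, rendering physics, splits."""

import dataclasses

import numpy as np
import pytest

from chorioseg import (
    PhantomParams,
    generate_boundaries,
    generate_dataset,
    render_bscan,
)


class TestGenerateBoundaries:
    def test_zero_curvature_gives_constant_boundaries(self, clean_params):
        params = dataclasses.replace(clean_params, curvature_amplitude=0.0)
        bounds = generate_boundaries(params)
        for name, depth in zip(("ilm", "rpe", "csi"), params.mean_depths):
            assert np.allclose(bounds[name], depth)

    def test_same_seed_same_boundaries(self, noisy_params):
        a = generate_boundaries(noisy_params)
        b = generate_boundaries(noisy_params)
        for name in ("ilm", "rpe", "csi"):
            np.testing.assert_array_equal(a[name], b[name])

    def test_different_seed_differs(self, noisy_params):
        a = generate_boundaries(noisy_params)
        b = generate_boundaries(noisy_params.with_seed(noisy_params.seed + 1))
        assert not np.allclose(a.ilm, b.ilm, equal_nan=True)

    @pytest.mark.parametrize("seed", range(10))
    def test_ordering_enforced_at_every_column(self, seed):
        params = PhantomParams(width=128, height=256,
                               mean_depths=(50.0, 120.0, 200.0),
                               curvature_amplitude=40.0,
                               curvature_smoothness=20.0, seed=seed)
        bounds = generate_boundaries(params)
        ok = bounds.present_mask()
        assert (bounds.rpe[ok] - bounds.ilm[ok]).min() > 0
        assert (bounds.csi[ok] - bounds.rpe[ok]).min() > 0

    def test_missing_only_in_margins(self, noisy_params):
        bounds = generate_boundaries(noisy_params)
        margin = noisy_params.missing_margin
        missing = bounds.missing_mask()
        interior = missing[margin:-margin]
        assert not interior.any()
        assert missing.any()  # with p=0.5 over 2*6 columns this is near-certain

    def test_non_increasing_depths_rejected(self, clean_params):
        bad = dataclasses.replace(clean_params, mean_depths=(30.0, 18.0, 44.0))
        with pytest.raises(ValueError, match="strictly increasing"):
            generate_boundaries(bad)


class TestRenderBscan:
    def test_noise_free_transitions_at_boundary_rows(self, clean_params):
        params = dataclasses.replace(clean_params, curvature_amplitude=0.0)
        bounds = generate_boundaries(params)
        scan = render_bscan(params, bounds)
        v = params.region_intensities
        ilm, rpe, csi = (int(d) for d in params.mean_depths)
        col = scan.pixels[:, 0]
        assert np.allclose(col[:ilm], v[0])
        assert np.allclose(col[ilm:rpe], v[1])
        assert np.allclose(col[rpe:csi], v[2])
        assert np.allclose(col[csi:], v[3])

    def test_unit_shadow_attenuation_is_identity(self, clean_params):
        with_shadows = dataclasses.replace(
            clean_params, shadow_count=4, shadow_width=6, shadow_attenuation=1.0)
        without = dataclasses.replace(clean_params, shadow_count=0)
        bounds = generate_boundaries(clean_params)
        np.testing.assert_array_equal(
            render_bscan(with_shadows, bounds).pixels,
            render_bscan(without, bounds).pixels)

    def test_determinism(self, noisy_params):
        bounds = generate_boundaries(noisy_params)
        a = render_bscan(noisy_params, bounds)
        b = render_bscan(noisy_params, bounds)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_choroid_mean_matches_closed_form(self, clean_params):
        """Monte-Carlo: speckle is unit-mean, so the choroid-band average
        equals intensity times mean attenuation within 3 standard errors."""
        params = dataclasses.replace(
            clean_params, curvature_amplitude=0.0, speckle_level=0.2,
            attenuation_rate=0.004, shadow_count=0)
        rpe, csi = int(params.mean_depths[1]), int(params.mean_depths[2])
        rows = np.arange(rpe, csi)
        expected = params.region_intensities[2] * np.mean(
            np.exp(-params.attenuation_rate * rows))
        means = []
        for seed in range(20):
            p = params.with_seed(seed)
            scan = render_bscan(p, generate_boundaries(p))
            means.append(scan.pixels[rpe:csi].mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se + 1e-9


class TestGenerateDataset:
    def test_study_protocol_counts(self):
        """50 participants x 6 scans at 80/20 -> 240 train / 60 validation."""
        params = PhantomParams(width=64, height=48,
                               mean_depths=(12.0, 22.0, 34.0),
                               missing_margin=0, seed=0)
        entries = generate_dataset(50, 6, 0.8, params)
        tags = [e.split_tag for e in entries]
        assert len(entries) == 300
        assert tags.count("train") == 240
        assert tags.count("validation") == 60

    def test_evaluation_manifest_counts(self):
        params = PhantomParams(width=64, height=48,
                               mean_depths=(12.0, 22.0, 34.0),
                               missing_margin=0, seed=0)
        entries = generate_dataset(49, 6, None, params)
        assert len(entries) == 294
        assert all(e.split_tag == "evaluation" for e in entries)

    def test_participant_disjoint_split(self):
        params = PhantomParams(width=64, height=48,
                               mean_depths=(12.0, 22.0, 34.0), seed=3)
        entries = generate_dataset(10, 3, 0.5, params)
        train = {e.participant_id for e in entries if e.split_tag == "train"}
        val = {e.participant_id for e in entries if e.split_tag == "validation"}
        assert train and val
        assert not train & val

    def test_two_participants_half_split(self):
        params = PhantomParams(width=64, height=48,
                               mean_depths=(12.0, 22.0, 34.0), seed=0)
        entries = generate_dataset(2, 4, 0.5, params)
        train = [e for e in entries if e.split_tag == "train"]
        val = [e for e in entries if e.split_tag == "validation"]
        assert len(train) == len(val) == 4

    def test_determinism_and_ordering_everywhere(self):
        params = PhantomParams(width=64, height=48,
                               mean_depths=(12.0, 22.0, 34.0), seed=11,
                               missing_margin=4)
        a = generate_dataset(4, 2, 0.5, params)
        b = generate_dataset(4, 2, 0.5, params)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.scan.pixels, eb.scan.pixels)
            ok = ea.boundaries.present_mask()
            assert ((ea.boundaries.ilm < ea.boundaries.rpe)
                    & (ea.boundaries.rpe < ea.boundaries.csi))[ok].all()

    def test_too_few_participants_rejected(self):
        params = PhantomParams(width=64, height=48,
                               mean_depths=(12.0, 22.0, 34.0))
        with pytest.raises(ValueError, match="participants"):
            generate_dataset(1, 6, 0.8, params)
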