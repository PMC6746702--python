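"""Shared fixtures: small phantoms exercised across the test modules."""

import numpy as np
import pytest

from chorioseg import PhantomParams, generate_boundaries, render_bscan
from chorioseg.core import BoundarySet, BScan


@pytest.fixture
def clean_params():
    """Small noise-free phantom: no speckle, attenuation, shadows or gaps."""
    return PhantomParams(
        width=96, height=64, mean_depths=(18.0, 30.0, 44.0),
        curvature_amplitude=3.0, curvature_smoothness=30.0,
        speckle_level=0.0, attenuation_rate=0.0, shadow_count=0,
        missing_margin=0, seed=7,
    )


@pytest.fixture
def noisy_params(clean_params):
    import dataclasses
    return dataclasses.replace(
        clean_params, speckle_level=0.25, attenuation_rate=0.004,
        shadow_count=2, shadow_width=5, missing_margin=6,
    )


@pytest.fixture
def clean_scan(clean_params):
    boundaries = generate_boundaries(clean_params)
    return render_bscan(clean_params, boundaries, "clean"), boundaries


def staircase_boundaries(width: int, depths=(18, 30, 44),
                         period: int = 8) -> BoundarySet:
    """Integer-valued boundaries moving at most 1 px per column.

    A gentle triangular wave around each mean depth; useful when a test
    needs ground truth that a monotone-column graph path can match exactly.
    """
    c = np.arange(width)
    tri = np.abs(((c // period) % 4) - 2) - 1  # +1, 0, -1, 0 jump pattern
    wave = np.cumsum(np.where(c % period == 0, tri, 0))  # integers, |step| <= 1
    wave = np.clip(wave, -3, 3)
    return BoundarySet(*(d + wave.astype(float) for d in depths))


@pytest.fixture
def staircase_scan(clean_params):
    import dataclasses
    bounds = staircase_boundaries(clean_params.width)
    params = dataclasses.replace(clean_params, curvature_amplitude=0.0)
    return render_bscan(params, bounds, "staircase"), bounds
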