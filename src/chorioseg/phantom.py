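"""Synthetic chorio-retinal B-scan phantoms with known ground truth.

The clinical dataset behind this line of work (EDI spectral-domain OCT of
children, 1536 x 496 px B-scans) is private, so every downstream stage is
exercised on phantoms that emulate its gross structure: three ordered,
smoothly curved boundaries (ILM, RPE, CSI) dividing each column into four
intensity regions (vitreous, retina, choroid, sclera), multiplicative
speckle, depth attenuation, vertical vessel shadows, and occasional missing
annotations near the lateral image edges.

Boundary curves are sums of a few random-phase sinusoids whose wavelengths
are tied to a correlation length, which gives smooth anatomy-like undulation
with a controllable slope.  Ordering is enforced by clamping each deeper
boundary at least ``MIN_SEPARATION`` pixels below the one above it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BOUNDARY_NAMES,
    BScan,
    BoundarySet,
    DEFAULT_SCALE_HORIZONTAL,
    DEFAULT_SCALE_VERTICAL,
)

__all__ = ["PhantomParams", "generate_boundaries", "render_bscan",
           "generate_scan", "generate_dataset", "DatasetEntry"]

#: Minimum vertical separation (pixels) enforced between adjacent boundaries.
MIN_SEPARATION = 2.0

#: Probability that an edge-margin column loses a given boundary annotation.
MISSING_PROB = 0.5


@dataclass(frozen=True)
class PhantomParams:
    """Generative parameters of one phantom B-scan.

    Defaults mimic the study acquisition: 1536 x 496 px with the retina in
    the upper half, moderate speckle, depth attenuation and a few vessel
    shadows.  ``mean_depths`` are the mean rows of (ILM, RPE, CSI), top to
    bottom.
    """

    width: int = 1536
    height: int = 496
    mean_depths: tuple[float, float, float] = (150.0, 220.0, 320.0)
    curvature_amplitude: float = 12.0
    curvature_smoothness: float = 300.0  # correlation length, columns
    region_intensities: tuple[float, float, float, float] = (10.0, 150.0, 110.0, 80.0)
    speckle_level: float = 0.3
    attenuation_rate: float = 0.002  # per-row exponential decay
    shadow_count: int = 3
    shadow_width: int = 12
    shadow_attenuation: float = 0.5
    missing_margin: int = 30
    seed: int = 0

    def validated(self) -> "PhantomParams":
        d = np.asarray(self.mean_depths, dtype=float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("mean_depths must be strictly increasing (ILM < RPE < CSI)")
        if d.min() <= 0 or d.max() >= self.height:
            raise ValueError("mean_depths must lie strictly inside (0, height)")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("width and height must be positive")
        if self.speckle_level < 0 or self.attenuation_rate < 0:
            raise ValueError("speckle_level and attenuation_rate must be >= 0")
        if not (0.0 <= self.shadow_attenuation <= 1.0):
            raise ValueError("shadow_attenuation must lie in [0, 1]")
        if self.shadow_count < 0 or self.shadow_width < 0 or self.missing_margin < 0:
            raise ValueError("shadow_count, shadow_width, missing_margin must be >= 0")
        return self

    def with_seed(self, seed: int) -> "PhantomParams":
        return dataclasses.replace(self, seed=int(seed))

    @classmethod
    def scaled_to(cls, width: int, height: int, **overrides) -> "PhantomParams":
        """Default parameters rescaled from the study geometry (1536 x 496).

        Depths, curvature amplitude and the per-row attenuation scale with
        height; lateral lengths (smoothness, shadow width, edge margins)
        scale with width.  Explicit ``overrides`` win.
        """
        base = cls()
        sy = height / base.height
        sx = width / base.width
        scaled = dict(
            width=width,
            height=height,
            mean_depths=tuple(round(d * sy, 1) for d in base.mean_depths),
            curvature_amplitude=base.curvature_amplitude * sy,
            curvature_smoothness=max(base.curvature_smoothness * sx, 4.0),
            attenuation_rate=base.attenuation_rate / sy,
            shadow_width=max(int(round(base.shadow_width * sx)), 1),
            missing_margin=int(round(base.missing_margin * sx)),
        )
        scaled.update(overrides)
        return cls(**scaled)


def _smooth_curve(rng: np.random.Generator, width: int, amplitude: float,
                  corr_length: float) -> np.ndarray:
    """One smooth zero-mean undulation: 2-4 random-phase sinusoids."""
    if amplitude == 0:
        return np.zeros(width)
    x = np.arange(width, dtype=float)
    n_waves = int(rng.integers(2, 5))
    curve = np.zeros(width)
    for _ in range(n_waves):
        # wavelengths no shorter than the correlation length
        wavelength = corr_length * rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        weight = rng.uniform(0.5, 1.0)
        curve += weight * np.sin(2 * np.pi * x / wavelength + phase)
    curve *= amplitude / max(np.abs(curve).max(), 1e-12)
    return curve


def generate_boundaries(params: PhantomParams) -> BoundarySet:
    """Draw three smooth ordered boundary curves for one phantom.

    Deterministic given ``params.seed``.  Columns within ``missing_margin``
    of either lateral edge lose each annotation independently with
    probability 0.5, emulating edge shadows in the clinical scans.
    """
    params = params.validated()
    rng = np.random.default_rng(params.seed)
    curves = []
    for depth in params.mean_depths:
        curve = depth + _smooth_curve(
            rng, params.width, params.curvature_amplitude, params.curvature_smoothness
        )
        curves.append(curve)
    # enforce ordering and image bounds by construction
    curves[0] = np.clip(curves[0], 1.0, params.height - 3 * MIN_SEPARATION)
    for i in (1, 2):
        upper = curves[i - 1]
        lo = upper + MIN_SEPARATION
        hi = params.height - 1 - (2 - i) * MIN_SEPARATION
        curves[i] = np.clip(np.maximum(curves[i], lo), None, hi)
        curves[i] = np.maximum(curves[i], lo)  # hi-clip may not undo ordering here
    ilm, rpe, csi = curves

    bs = BoundarySet(ilm, rpe, csi)
    if params.missing_margin > 0:
        margin = min(params.missing_margin, params.width)
        edge_cols = np.r_[np.arange(margin),
                          np.arange(params.width - margin, params.width)]
        edge_cols = np.unique(edge_cols)
        for name in BOUNDARY_NAMES:
            drop = rng.random(edge_cols.size) < MISSING_PROB
            getattr(bs, name)[edge_cols[drop]] = np.nan
    bs.validate(params.height)
    return bs


def _region_image(params: PhantomParams, boundaries: BoundarySet) -> np.ndarray:
    """Noise-free base image: each pixel takes its region's mean intensity."""
    rows = np.arange(params.height, dtype=float)[:, None]
    v_vit, v_ret, v_cho, v_scl = params.region_intensities
    # fall back to the mean depths for unannotated columns so the image
    # still shows tissue there (only the annotation is missing)
    ilm = np.where(np.isnan(boundaries.ilm), params.mean_depths[0], boundaries.ilm)
    rpe = np.where(np.isnan(boundaries.rpe), params.mean_depths[1], boundaries.rpe)
    csi = np.where(np.isnan(boundaries.csi), params.mean_depths[2], boundaries.csi)
    img = np.full((params.height, params.width), v_vit, dtype=float)
    img = np.where(rows >= ilm[None, :], v_ret, img)
    img = np.where(rows >= rpe[None, :], v_cho, img)
    img = np.where(rows >= csi[None, :], v_scl, img)
    return img


def render_bscan(params: PhantomParams, boundaries: BoundarySet,
                 identifier: str = "phantom") -> BScan:
    """Render the intensity image implied by a boundary set.

    Pipeline per pixel: region mean intensity, times ``exp(-rate * row)``
    depth attenuation, times unit-mean gamma speckle, times a shadow factor
    below the ILM inside randomly placed vertical bands; clipped to
    [0, 255].  Deterministic given ``params.seed``.
    """
    params = params.validated()
    if boundaries.width != params.width:
        raise ValueError("boundaries width does not match params.width")
    rng = np.random.default_rng(params.seed + 1)  # independent of the curves
    img = _region_image(params, boundaries)

    rows = np.arange(params.height, dtype=float)[:, None]
    img = img * np.exp(-params.attenuation_rate * rows)

    if params.speckle_level > 0:
        # unit-mean gamma speckle with std = speckle_level
        shape = 1.0 / params.speckle_level ** 2
        img = img * rng.gamma(shape, 1.0 / shape, size=img.shape)

    if params.shadow_count > 0 and params.shadow_width > 0:
        ilm = np.where(np.isnan(boundaries.ilm), params.mean_depths[0], boundaries.ilm)
        starts = rng.integers(0, max(params.width - params.shadow_width, 1),
                              size=params.shadow_count)
        below_ilm = rows >= ilm[None, :]
        for s in starts:
            band = np.zeros(params.width, dtype=bool)
            band[s:s + params.shadow_width] = True
            factor = np.where(below_ilm & band[None, :],
                              params.shadow_attenuation, 1.0)
            img = img * factor

    return BScan(np.clip(img, 0.0, 255.0),
                 DEFAULT_SCALE_VERTICAL, DEFAULT_SCALE_HORIZONTAL, identifier)


def generate_scan(params: PhantomParams,
                  identifier: str = "phantom") -> tuple[BScan, BoundarySet]:
    """Convenience: boundaries + rendered scan from one parameter set."""
    boundaries = generate_boundaries(params)
    return render_bscan(params, boundaries, identifier), boundaries


@dataclass
class DatasetEntry:
    """One generated scan with its provenance."""

    scan: BScan
    boundaries: BoundarySet
    participant_id: str
    split_tag: str  # train | validation | evaluation


def _participant_params(base: PhantomParams, rng: np.random.Generator) -> PhantomParams:
    """Per-participant anatomical variation: jitter the mean layer depths."""
    d = np.asarray(base.mean_depths, dtype=float)
    jitter = rng.uniform(-0.08, 0.08, size=3) * d
    d = np.sort(d + jitter)
    d = np.clip(d, 2 * MIN_SEPARATION, base.height - 2 * MIN_SEPARATION)
    for i in (1, 2):
        d[i] = max(d[i], d[i - 1] + 2 * MIN_SEPARATION)
    return dataclasses.replace(base, mean_depths=tuple(d))


def generate_dataset(n_participants: int, scans_per_participant: int,
                     split_fraction: float | None, params: PhantomParams,
                     ) -> list[DatasetEntry]:
    """Generate a participant-disjoint phantom dataset.

    With ``split_fraction`` f, participants are randomly partitioned into
    train (round(f * n)) and validation (the rest); with ``None`` every scan
    is tagged ``evaluation`` (the study's held-out set B).  Splitting is by
    participant, so no participant contributes scans to both partitions.
    Deterministic given ``params.seed``.
    """
    params = params.validated()
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if scans_per_participant < 1:
        raise ValueError("need at least one scan per participant")
    if split_fraction is not None and not (0.0 < split_fraction < 1.0):
        raise ValueError("split_fraction must lie in (0, 1)")

    rng = np.random.default_rng(params.seed)
    order = rng.permutation(n_participants)
    if split_fraction is None:
        tags = {int(p): "evaluation" for p in order}
    else:
        n_train = int(round(n_participants * split_fraction))
        n_train = min(max(n_train, 1), n_participants - 1)
        tags = {int(p): ("train" if i < n_train else "validation")
                for i, p in enumerate(order)}

    entries: list[DatasetEntry] = []
    for p in range(n_participants):
        pid = f"P{p:03d}"
        p_rng = np.random.default_rng((params.seed, 17, p))
        p_params = _participant_params(params, p_rng)
        for s in range(scans_per_participant):
            scan_seed = int(p_rng.integers(0, 2**31 - 1))
            sp = p_params.with_seed(scan_seed)
            scan, bounds = generate_scan(sp, identifier=f"{pid}_s{s}")
            entries.append(DatasetEntry(scan, bounds, pid, tags[p]))
    return entries
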