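"""Pre-processing: attenuation compensation, area masks, zeroing, flips.

Attenuation compensation (``contrast_enhance``) divides the local
backscatter at each depth by (twice) the signal remaining below it,
compensating the exponential depth decay of OCT and boosting the weakly
contrasted choroid-sclera transition:

    E(i, j) = I(i, j)^n / (2 * sum_{k>=i} I(k, j)^n + eps)

with exponent ``n = 2`` by default.  The output is rescaled to [0, 255] by
the per-image maximum so enhanced and raw images share one intensity range.
"""

from __future__ import annotations

import numpy as np

from .core import (
    BScan,
    BoundarySet,
    CHOROID,
    RETINA,
    SCLERA,
    VITREOUS,
    round_half_up,
)

__all__ = [
    "contrast_enhance",
    "boundaries_to_area_mask",
    "area_mask_to_boundaries",
    "zero_missing_columns",
    "random_horizontal_flip",
    "validate_area_mask",
]


def contrast_enhance(scan: BScan, exponent: float = 2.0, floor: float = 1e-8,
                     rescale: bool = True) -> BScan:
    """Attenuation-compensation contrast enhancement of one B-scan.

    ``exponent`` is the signal exponent n >= 1; ``floor`` is the small
    positive stabiliser added to the cumulative tail sum (it also makes
    all-zero columns map to zero instead of dividing by zero).  With
    ``rescale=False`` the raw compensation ratio in [0, ~0.5] is returned,
    which is convenient for closed-form checks.
    """
    if exponent < 1:
        raise ValueError("exponent must be >= 1")
    if floor <= 0:
        raise ValueError("floor must be positive")
    power = scan.pixels ** exponent
    # tail sum from the current row (inclusive) to the bottom of the column
    tail = np.cumsum(power[::-1, :], axis=0)[::-1, :]
    enhanced = power / (2.0 * tail + floor)
    if rescale:
        peak = enhanced.max()
        if peak > 0:
            enhanced = enhanced * (255.0 / peak)
    out = scan.copy()
    out.pixels = enhanced
    return out


def boundaries_to_area_mask(boundaries: BoundarySet, height: int,
                            width: int | None = None) -> np.ndarray:
    """Rasterise boundaries into per-pixel area labels.

    Row r of column c is vitreous for r < ILM(c), retina for
    ILM(c) <= r < RPE(c), choroid for RPE(c) <= r < CSI(c), else sclera;
    fractional boundary rows are rounded half-up.  Columns missing any
    boundary are labelled entirely vitreous (the training convention for
    unannotated columns).
    """
    if width is None:
        width = boundaries.width
    if width != boundaries.width:
        raise ValueError("width does not match the boundary set")
    rows = np.arange(height)[:, None]
    ilm = round_half_up(boundaries.ilm)
    rpe = round_half_up(boundaries.rpe)
    csi = round_half_up(boundaries.csi)
    mask = np.full((height, width), VITREOUS, dtype=np.uint8)
    ok = boundaries.present_mask()
    with np.errstate(invalid="ignore"):
        mask[(rows >= ilm[None, :]) & ok[None, :]] = RETINA
        mask[(rows >= rpe[None, :]) & ok[None, :]] = CHOROID
        mask[(rows >= csi[None, :]) & ok[None, :]] = SCLERA
    return mask


def area_mask_to_boundaries(mask: np.ndarray) -> BoundarySet:
    """Inverse of :func:`boundaries_to_area_mask` for fully labelled columns.

    Each boundary is the first row of its deeper region; columns without a
    given region transition are marked missing.
    """
    height, width = mask.shape
    out = np.full((3, width), np.nan)
    for b, label in enumerate((RETINA, CHOROID, SCLERA)):
        hit = mask == label
        any_hit = hit.any(axis=0)
        first = np.argmax(hit, axis=0).astype(float)
        out[b, any_hit] = first[any_hit]
    return BoundarySet(out[0], out[1], out[2])


def validate_area_mask(mask: np.ndarray) -> None:
    """Check the per-column monotone label invariant (vitreous -> sclera)."""
    if mask.min() < VITREOUS or mask.max() > SCLERA:
        raise ValueError("area mask labels must lie in 0..3")
    if (np.diff(mask.astype(int), axis=0) < 0).any():
        raise ValueError("area mask labels must be monotone down each column")


def zero_missing_columns(scan: BScan, boundaries: BoundarySet) -> BScan:
    """Zero every image column lacking at least one boundary annotation."""
    if boundaries.width != scan.width:
        raise ValueError("boundaries width does not match the scan")
    out = scan.copy()
    out.pixels[:, boundaries.missing_mask()] = 0.0
    return out


def random_horizontal_flip(image: np.ndarray, mask: np.ndarray,
                           rng: np.random.Generator,
                           probability: float = 0.5,
                           ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Flip image and mask together along columns with the given probability.

    Returns the (possibly flipped) pair plus whether the flip happened.
    The draw always consumes exactly one uniform variate, so augmentation
    streams are reproducible regardless of the outcome.
    """
    if image.shape[-2:] != mask.shape[-2:]:
        raise ValueError("image and mask shapes do not match")
    flipped = bool(rng.random() < probability)
    if flipped:
        image = image[..., ::-1].copy()
        mask = mask[..., ::-1].copy()
    return image, mask, flipped
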