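"""Core domain containers for chorio-retinal OCT segmentation.

Conventions used throughout the package:

* Images are 2-D ``float64`` arrays indexed ``[row, column]`` with the
  origin at the top-left; intensities live in ``[0, 255]``.
* A boundary position is the (possibly fractional) row index of the first
  pixel of the deeper region, 0-based.  Missing annotations are ``NaN``.
* The three boundaries of interest, top to bottom, are the inner limiting
  membrane (ILM), the outer retinal pigment epithelium boundary (RPE) and
  the choroid-scleral interface (CSI).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "BOUNDARY_NAMES",
    "REGION_NAMES",
    "VITREOUS",
    "RETINA",
    "CHOROID",
    "SCLERA",
    "DEFAULT_SCALE_VERTICAL",
    "DEFAULT_SCALE_HORIZONTAL",
    "BScan",
    "BoundarySet",
    "CropRegion",
    "round_half_up",
]

BOUNDARY_NAMES = ("ilm", "rpe", "csi")
REGION_NAMES = ("vitreous", "retina", "choroid", "sclera")

VITREOUS, RETINA, CHOROID, SCLERA = 0, 1, 2, 3

#: Study acquisition scales (Heidelberg Spectralis EDI protocol), µm / pixel.
DEFAULT_SCALE_VERTICAL = 3.9
DEFAULT_SCALE_HORIZONTAL = 5.7


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to the nearest integer with halves going up (toward +inf).

    Used wherever a fractional boundary row must be mapped to a pixel row;
    ``np.round`` banker's rounding would make the mapping parity-dependent.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class BScan:
    """A single grayscale OCT cross-section with physical pixel scales."""

    pixels: np.ndarray
    scale_vertical: float = DEFAULT_SCALE_VERTICAL
    scale_horizontal: float = DEFAULT_SCALE_HORIZONTAL
    identifier: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) == 0:
            raise ValueError("BScan pixels must be a non-empty 2-D array")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("BScan intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self) -> "BScan":
        return replace(self, pixels=self.pixels.copy())


@dataclass
class BoundarySet:
    """Per-column row positions of the ILM, RPE and CSI (NaN = missing)."""

    ilm: np.ndarray
    rpe: np.ndarray
    csi: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=float)
        self.rpe = np.asarray(self.rpe, dtype=float)
        self.csi = np.asarray(self.csi, dtype=float)
        if not (self.ilm.shape == self.rpe.shape == self.csi.shape):
            raise ValueError("boundary arrays must share one length")
        if self.ilm.ndim != 1:
            raise ValueError("boundary arrays must be 1-D (one value per column)")

    @property
    def width(self) -> int:
        return self.ilm.shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in BOUNDARY_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        for name in BOUNDARY_NAMES:
            yield name, getattr(self, name)

    def present_mask(self) -> np.ndarray:
        """Boolean mask of columns where all three boundaries are annotated."""
        return ~(np.isnan(self.ilm) | np.isnan(self.rpe) | np.isnan(self.csi))

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of columns lacking at least one boundary."""
        return ~self.present_mask()

    def validate(self, height: int | None = None) -> None:
        """Check the anatomical ordering ILM < RPE < CSI wherever annotated.

        Raises ``ValueError`` naming the first offending column.
        """
        ok = self.present_mask()
        bad = ok & ~((self.ilm < self.rpe) & (self.rpe < self.csi))
        if bad.any():
            col = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"boundary ordering ILM < RPE < CSI violated at column {col}"
            )
        if height is not None:
            for name, rows in self.items():
                vals = rows[~np.isnan(rows)]
                if vals.size and (vals.min() < 0 or vals.max() > height - 1):
                    raise ValueError(
                        f"boundary '{name}' leaves the image (height {height})"
                    )

    def copy(self) -> "BoundarySet":
        return BoundarySet(self.ilm.copy(), self.rpe.copy(), self.csi.copy())


@dataclass(frozen=True)
class CropRegion:
    """Column margins excluded from patch sampling and error evaluation.

    The study excluded roughly 100 columns at the left and 250 at the right
    of each 1536-wide scan (optic nerve head and edge shadows).
    """

    left_margin: int = 100
    right_margin: int = 250

    def __post_init__(self) -> None:
        if self.left_margin < 0 or self.right_margin < 0:
            raise ValueError("crop margins must be non-negative")

    def columns(self, width: int) -> np.ndarray:
        """Indices of the evaluated columns for an image of this width."""
        if self.left_margin + self.right_margin >= width:
            raise ValueError(
                f"crop ({self.left_margin}, {self.right_margin}) leaves no "
                f"columns of a width-{width} image"
            )
        return np.arange(self.left_margin, width - self.right_margin)

    def n_columns(self, width: int) -> int:
        return width - self.left_margin - self.right_margin
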