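"""Patch construction for the patch-based classification method.

Each training patch is labelled by the boundary its anchor pixel sits on
(ILM, RPE, CSI) or as background (BG).  The anchor convention follows the
boundary-centred scheme of the CNN-graph-search literature: for an even
``height x width`` patch the anchor occupies position
``(height/2 - 1, width/2 - 1)`` -- one pixel above and to the left of the
patch centre.  Out-of-image content is mirror padded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core import BScan, BoundarySet, CropRegion, round_half_up

__all__ = ["PatchSpec", "LabelledPatch", "extract_patch", "extract_patches",
           "sample_training_patches", "dense_anchor_iterator",
           "PATCH_CLASSES"]

#: Fixed class order used by every patch classifier head.
PATCH_CLASSES = ("ilm", "rpe", "csi", "bg")

#: BG anchors are kept at least this many rows away from every boundary row.
BG_EXCLUSION_PX = 1


@dataclass(frozen=True)
class PatchSpec:
    """Patch geometry; both dimensions must be even."""

    height: int = 32
    width: int = 32

    def __post_init__(self) -> None:
        if self.height % 2 or self.width % 2:
            raise ValueError("patch height and width must be even")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("patch dimensions must be positive")

    @property
    def anchor_offset(self) -> tuple[int, int]:
        """Anchor position within the patch (0-based)."""
        return self.height // 2 - 1, self.width // 2 - 1


@dataclass(frozen=True)
class LabelledPatch:
    pixels: np.ndarray
    label: str
    source: tuple[str, int, int]  # scan id, anchor row, anchor column

    def __post_init__(self) -> None:
        if self.label not in PATCH_CLASSES:
            raise ValueError(f"unknown patch label {self.label!r}")


def _padded(scan: BScan, spec: PatchSpec) -> np.ndarray:
    """Mirror-pad the scan far enough for any in-image anchor."""
    return np.pad(scan.pixels, ((spec.height, spec.height),
                                (spec.width, spec.width)), mode="reflect")


def extract_patch(scan: BScan, anchor: tuple[int, int], spec: PatchSpec,
                  _padded_pixels: np.ndarray | None = None) -> np.ndarray:
    """Extract one patch with the anchor at (height/2 - 1, width/2 - 1).

    ``_padded_pixels`` lets callers reuse one mirror-padded copy when
    extracting many patches from the same scan.
    """
    r, c = int(anchor[0]), int(anchor[1])
    ar, ac = spec.anchor_offset
    padded = _padded(scan, spec) if _padded_pixels is None else _padded_pixels
    r0 = r - ar + spec.height
    c0 = c - ac + spec.width
    return padded[r0:r0 + spec.height, c0:c0 + spec.width].copy()


def extract_patches(scan: BScan, anchors: np.ndarray,
                    spec: PatchSpec) -> np.ndarray:
    """Vectorised extraction of many patches: (n, height, width) array."""
    padded = _padded(scan, spec)
    ar, ac = spec.anchor_offset
    anchors = np.asarray(anchors, dtype=int)
    out = np.empty((len(anchors), spec.height, spec.width), dtype=padded.dtype)
    for i, (r, c) in enumerate(anchors):
        r0 = r - ar + spec.height
        c0 = c - ac + spec.width
        out[i] = padded[r0:r0 + spec.height, c0:c0 + spec.width]
    return out


def sample_training_patches(scan: BScan, boundaries: BoundarySet,
                            spec: PatchSpec, crop: CropRegion,
                            rng: np.random.Generator) -> list[LabelledPatch]:
    """Sample class-balanced training patches from one annotated scan.

    Per eligible column (inside the crop, all three boundaries present):
    one patch anchored on each rounded boundary row plus one background
    patch at a uniformly drawn row at least ``BG_EXCLUSION_PX`` rows from
    every boundary.  Columns with a missing boundary are skipped, keeping
    the four classes exactly balanced.
    """
    padded = _padded(scan, spec)
    present = boundaries.present_mask()
    patches: list[LabelledPatch] = []
    height = scan.height
    for c in crop.columns(scan.width):
        if not present[c]:
            continue
        b_rows = [int(round_half_up(boundaries[name][c]))
                  for name in ("ilm", "rpe", "csi")]
        for name, r in zip(("ilm", "rpe", "csi"), b_rows):
            patches.append(LabelledPatch(
                extract_patch(scan, (r, c), spec, padded), name,
                (scan.identifier, r, int(c))))
        allowed = np.ones(height, dtype=bool)
        for r in b_rows:
            lo = max(r - BG_EXCLUSION_PX, 0)
            allowed[lo:r + BG_EXCLUSION_PX + 1] = False
        candidates = np.flatnonzero(allowed)
        r_bg = int(rng.choice(candidates))
        patches.append(LabelledPatch(
            extract_patch(scan, (r_bg, c), spec, padded), "bg",
            (scan.identifier, r_bg, int(c))))
    return patches


def dense_anchor_iterator(scan: BScan, spec: PatchSpec,
                          crop: CropRegion) -> Iterator[tuple[int, int]]:
    """Row-major anchors covering every pixel of the crop region.

    Yields ``scan.height * crop.n_columns(scan.width)`` anchors starting at
    ``(0, crop.left_margin)``; used to build dense probability maps.
    """
    cols = crop.columns(scan.width)
    for r in range(scan.height):
        for c in cols:
            yield (r, int(c))
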