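"""Evaluation: post-segmentation Dice, signed/absolute boundary errors.

All quantities are computed over a cropped column range (the study excluded
~100 columns at the left and ~250 at the right of each scan).  Dice is
always computed post-segmentation: region masks are rebuilt from the
boundary positions of both prediction and truth, so a perfect boundary
yields Dice 100 regardless of raw network output.  Boundary errors are
reported in pixels against the un-rounded truth; positive mean error means
the prediction lies deeper (larger row index) than the truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BOUNDARY_NAMES, REGION_NAMES, BoundarySet, CropRegion
from .preprocess import boundaries_to_area_mask

__all__ = ["ScanReport", "EvalReport", "dice_percent", "dice_all_regions",
           "boundary_errors", "aggregate", "pixels_to_mm"]

logger = logging.getLogger(__name__)


def _crop_boundaries(bs: BoundarySet, crop: CropRegion, width: int) -> BoundarySet:
    cols = crop.columns(width)
    return BoundarySet(bs.ilm[cols], bs.rpe[cols], bs.csi[cols])


def dice_percent(pred: BoundarySet, truth: BoundarySet, region: int | str,
                 height: int, crop: CropRegion) -> float:
    """Post-segmentation Dice overlap percentage for one region.

    Region masks are rasterised from both boundary sets over the crop
    columns; Dice = 100 * 2|X n Y| / (|X| + |Y|), with the empty-empty
    case defined as 100.
    """
    if isinstance(region, str):
        region = REGION_NAMES.index(region)
    width = pred.width
    if truth.width != width:
        raise ValueError("prediction and truth widths differ")
    pred_c = _crop_boundaries(pred, crop, width)
    truth_c = _crop_boundaries(truth, crop, width)
    x = boundaries_to_area_mask(pred_c, height) == region
    y = boundaries_to_area_mask(truth_c, height) == region
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 100.0
    return 200.0 * int((x & y).sum()) / total


def dice_all_regions(pred: BoundarySet, truth: BoundarySet, height: int,
                     crop: CropRegion) -> dict[str, float]:
    return {name: dice_percent(pred, truth, i, height, crop)
            for i, name in enumerate(REGION_NAMES)}


def boundary_errors(pred: BoundarySet, truth: BoundarySet,
                    crop: CropRegion) -> dict[str, tuple[float, float]]:
    """Per-boundary (ME, MAE) in pixels over the crop columns.

    ME is the mean of (predicted row - true row): positive values mean the
    prediction sits deeper than the truth.  Truth must be annotated at
    every crop column; predictions are total by construction.
    """
    width = pred.width
    if truth.width != width:
        raise ValueError("prediction and truth widths differ")
    cols = crop.columns(width)
    out: dict[str, tuple[float, float]] = {}
    for name in BOUNDARY_NAMES:
        t = truth[name][cols]
        p = pred[name][cols]
        if np.isnan(t).any():
            raise ValueError(f"truth boundary '{name}' missing inside the crop")
        if np.isnan(p).any():
            raise ValueError(f"prediction boundary '{name}' missing inside the crop")
        diff = p - t
        out[name] = (float(diff.mean()), float(np.abs(diff).mean()))
    return out


@dataclass
class ScanReport:
    """Per-scan evaluation quantities."""

    scan_id: str
    dice: dict[str, float]              # region -> Dice %
    me: dict[str, float]                # boundary -> mean signed error, px
    mae: dict[str, float]               # boundary -> mean absolute error, px

    @classmethod
    def from_boundaries(cls, scan_id: str, pred: BoundarySet,
                        truth: BoundarySet, height: int,
                        crop: CropRegion) -> "ScanReport":
        errors = boundary_errors(pred, truth, crop)
        return cls(
            scan_id=scan_id,
            dice=dice_all_regions(pred, truth, height, crop),
            me={k: v[0] for k, v in errors.items()},
            mae={k: v[1] for k, v in errors.items()},
        )


@dataclass
class EvalReport:
    """Aggregate over scans: mean and per-B-scan standard deviation.

    The standard deviation is the sample (n-1) standard deviation of the
    per-scan means, one value per quantity -- the single-number spread a
    results table reports next to each mean.
    """

    scans: list[ScanReport]
    crop: CropRegion
    mean_dice: dict[str, float] = field(init=False)
    std_dice: dict[str, float] = field(init=False)
    mean_me: dict[str, float] = field(init=False)
    std_me: dict[str, float] = field(init=False)
    mean_mae: dict[str, float] = field(init=False)
    std_mae: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.scans:
            raise ValueError("cannot aggregate zero scans")
        if len(self.scans) == 1:
            logger.warning("aggregating a single scan: std reported as 0")

        def stats(values: list[float]) -> tuple[float, float]:
            arr = np.asarray(values, dtype=float)
            std = 0.0 if arr.size < 2 else float(arr.std(ddof=1))
            return float(arr.mean()), std

        self.mean_dice, self.std_dice = {}, {}
        for r in REGION_NAMES:
            self.mean_dice[r], self.std_dice[r] = stats(
                [s.dice[r] for s in self.scans])
        self.mean_me, self.std_me = {}, {}
        self.mean_mae, self.std_mae = {}, {}
        for b in BOUNDARY_NAMES:
            self.mean_me[b], self.std_me[b] = stats(
                [s.me[b] for s in self.scans])
            self.mean_mae[b], self.std_mae[b] = stats(
                [s.mae[b] for s in self.scans])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scans:
            row: dict[str, object] = {"scan": s.scan_id}
            row.update({f"dice_{r}": s.dice[r] for r in REGION_NAMES})
            row.update({f"me_{b}": s.me[b] for b in BOUNDARY_NAMES})
            row.update({f"mae_{b}": s.mae[b] for b in BOUNDARY_NAMES})
            rows.append(row)
        for label, dice, me, mae in (
                ("aggregate_mean", self.mean_dice, self.mean_me, self.mean_mae),
                ("aggregate_std", self.std_dice, self.std_me, self.std_mae)):
            row = {"scan": label}
            row.update({f"dice_{r}": dice[r] for r in REGION_NAMES})
            row.update({f"me_{b}": me[b] for b in BOUNDARY_NAMES})
            row.update({f"mae_{b}": mae[b] for b in BOUNDARY_NAMES})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "crop": {"left_margin": self.crop.left_margin,
                     "right_margin": self.crop.right_margin},
            "aggregate": {
                "mean_dice": self.mean_dice, "std_dice": self.std_dice,
                "mean_me": self.mean_me, "std_me": self.std_me,
                "mean_mae": self.mean_mae, "std_mae": self.std_mae,
            },
            "scans": [
                {"scan": s.scan_id, "dice": s.dice, "me": s.me, "mae": s.mae}
                for s in self.scans
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def aggregate(scans: list[ScanReport], crop: CropRegion) -> EvalReport:
    """Aggregate per-scan reports into means and per-B-scan stds."""
    return EvalReport(scans=scans, crop=crop)


def pixels_to_mm(n_pixels: float, scale_um_per_pixel: float) -> float:
    """Convert a pixel count to millimetres with a µm/pixel scale."""
    if n_pixels < 0:
        raise ValueError("pixel count must be non-negative")
    if scale_um_per_pixel <= 0:
        raise ValueError("scale must be positive")
    return n_pixels * scale_um_per_pixel / 1000.0
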