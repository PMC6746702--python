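"""On-disk formats: B-scan images, boundary CSVs, area-mask PNGs, manifests.

Formats are deliberately plain: 8-bit grayscale PNG/BMP/TIFF for images
(scales in a JSON sidecar next to the image), CSV with header
``column,ilm,rpe,csi`` for boundary annotations (empty cell = missing,
0-based columns, 3-decimal precision), label PNG with codes 0-3 for area
masks, and a JSON manifest tying scans to annotations, participants and
splits.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import (
    BScan,
    BoundarySet,
    DEFAULT_SCALE_HORIZONTAL,
    DEFAULT_SCALE_VERTICAL,
    SCLERA,
)

__all__ = [
    "read_bscan", "write_bscan",
    "read_boundaries", "write_boundaries",
    "read_area_mask", "write_area_mask",
    "write_probability_map", "read_probability_map",
    "ManifestEntry", "read_manifest", "write_manifest",
]

logger = logging.getLogger(__name__)

_SPLIT_TAGS = {"train", "validation", "evaluation"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_bscan(scan: BScan, path: str | Path) -> None:
    """Write an 8-bit grayscale image plus a JSON scale sidecar."""
    path = Path(path)
    iio.imwrite(path, np.round(scan.pixels).astype(np.uint8))
    meta = {
        "scale_vertical_um_per_px": scan.scale_vertical,
        "scale_horizontal_um_per_px": scan.scale_horizontal,
        "identifier": scan.identifier or path.stem,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_bscan(path: str | Path) -> BScan:
    """Read an 8-bit grayscale PNG/BMP/TIFF as a :class:`BScan`.

    RGB(A) input is converted to grayscale with a logged warning.  Pixel
    scales come from the JSON sidecar when present, otherwise the study
    defaults (3.9, 5.7) µm/px are assumed.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except OSError as exc:
        raise OSError(f"cannot read B-scan image {path}: {exc}") from exc
    if arr.ndim == 3:
        logger.warning("converting colour image %s to grayscale", path)
        arr = arr[..., :3].mean(axis=-1)
    arr = np.clip(np.asarray(arr, dtype=float), 0.0, 255.0)

    sv, sh = DEFAULT_SCALE_VERTICAL, DEFAULT_SCALE_HORIZONTAL
    ident = path.stem
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sv = float(meta.get("scale_vertical_um_per_px", sv))
        sh = float(meta.get("scale_horizontal_um_per_px", sh))
        ident = meta.get("identifier", ident)
    return BScan(arr, sv, sh, ident)


def write_boundaries(boundaries: BoundarySet, path: str | Path) -> None:
    """Write boundary rows as CSV (``column,ilm,rpe,csi``; blank = missing)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["column", "ilm", "rpe", "csi"])
        for c in range(boundaries.width):
            row = [c]
            for name in ("ilm", "rpe", "csi"):
                v = boundaries[name][c]
                row.append("" if np.isnan(v) else f"{v:.3f}")
            writer.writerow(row)


def read_boundaries(path: str | Path, width: int | None = None,
                    validate: bool = True) -> BoundarySet:
    """Read a boundary CSV; columns absent from the file stay missing.

    Raises ``ValueError`` naming the first column violating the anatomical
    ordering ILM < RPE < CSI.  ``validate=False`` skips that check, which
    is appropriate for model predictions (the three boundaries are
    delineated independently and a poor model may cross them; they should
    be scored, not rejected).
    """
    path = Path(path)
    rows: dict[int, tuple[float, float, float]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"column", "ilm", "rpe", "csi"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected CSV header column,ilm,rpe,csi")
        for rec in reader:
            c = int(rec["column"])
            vals = tuple(
                float(rec[k]) if rec[k] not in ("", None) else np.nan
                for k in ("ilm", "rpe", "csi")
            )
            rows[c] = vals
    max_col = max(rows) if rows else -1
    if width is None:
        width = max_col + 1
    if max_col >= width:
        raise ValueError(f"{path}: column {max_col} exceeds declared width {width}")
    arr = np.full((3, width), np.nan)
    for c, vals in rows.items():
        arr[:, c] = vals
    bs = BoundarySet(arr[0], arr[1], arr[2])
    if validate:
        bs.validate()
    return bs


def write_area_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write an area-label mask (codes 0-3) as an 8-bit PNG."""
    mask = np.asarray(mask)
    if mask.min() < 0 or mask.max() > SCLERA:
        raise ValueError("area mask labels must lie in 0..3")
    iio.imwrite(Path(path), mask.astype(np.uint8))


def read_area_mask(path: str | Path) -> np.ndarray:
    """Read an area-label mask PNG; rejects labels outside 0..3."""
    mask = np.asarray(iio.imread(Path(path)))
    if mask.ndim != 2:
        raise ValueError(f"{path}: area mask must be single-channel")
    if mask.max() > SCLERA:
        raise ValueError(f"{path}: label {int(mask.max())} outside 0..3")
    return mask.astype(np.uint8)


def write_probability_map(prob_map: np.ndarray, path: str | Path) -> None:
    """Dump a [0, 1] probability map as a 16-bit grayscale PNG."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    iio.imwrite(Path(path), np.round(prob_map * 65535).astype(np.uint16))


def read_probability_map(path: str | Path) -> np.ndarray:
    """Read a probability map written by :func:`write_probability_map`."""
    arr = np.asarray(iio.imread(Path(path)))
    if arr.dtype != np.uint16:
        raise ValueError(f"{path}: expected a 16-bit probability map")
    return arr.astype(float) / 65535.0


@dataclass(frozen=True)
class ManifestEntry:
    scan_path: str
    annotation_path: str
    participant_id: str
    split_tag: str


def write_manifest(entries: list[ManifestEntry], path: str | Path) -> None:
    payload = [
        {
            "scan": e.scan_path,
            "annotations": e.annotation_path,
            "participant": e.participant_id,
            "split": e.split_tag,
        }
        for e in entries
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_manifest(path: str | Path, check_files: bool = True) -> list[ManifestEntry]:
    """Read a dataset manifest, validating tags and file existence."""
    path = Path(path)
    payload = json.loads(path.read_text())
    entries = []
    for rec in payload:
        tag = rec["split"]
        if tag not in _SPLIT_TAGS:
            raise ValueError(f"{path}: unknown split tag {tag!r}")
        entry = ManifestEntry(rec["scan"], rec["annotations"],
                              rec["participant"], tag)
        if check_files:
            base = path.parent
            for p in (entry.scan_path, entry.annotation_path):
                if not (base / p).exists():
                    raise FileNotFoundError(f"{path}: missing referenced file {p}")
        entries.append(entry)
    return entries
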