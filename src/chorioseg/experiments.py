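"""End-to-end study protocols at phantom scale.

The clinical experiment trains on hundreds of 1536 x 496 B-scans; the
phantom protocol here reproduces its structure at a desk scale chosen to
keep a full run in minutes on one CPU: 128 x 256 px phantoms, 100
participants with one scan each (80 train / 20 validation, participant
disjoint), the standard U-Net trained for 20 epochs with
argmax-validation checkpoint selection, then full-chain segmentation and
Dice/ME/MAE evaluation of the 20 held-out phantoms over a proportionally
scaled crop region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core import CropRegion
from .evalmetrics import EvalReport, ScanReport, aggregate
from .nets import (
    SemanticModelConfig,
    TrainConfig,
    build_semantic_model,
    train_semantic_model,
)
from .boundarygraph import segment_scan
from .phantom import PhantomParams, generate_dataset
from .preprocess import boundaries_to_area_mask, zero_missing_columns

logger = logging.getLogger(__name__)

__all__ = ["scaled_phantom_params", "SCALED_CROP", "run_semantic_end_to_end"]

#: Crop used on 256-wide phantoms, the study's (100, 250) of 1536 columns
#: scaled proportionally.
SCALED_CROP = CropRegion(left_margin=17, right_margin=42)


def scaled_phantom_params(seed: int = 0) -> PhantomParams:
    """Phantom parameters for the 128 x 256 px scaled protocol.

    Depths, curvature, attenuation, shadow geometry and edge margins are
    the full-size defaults scaled by the resolution ratio; speckle level
    and region intensities are resolution independent.
    """
    return PhantomParams(
        width=256,
        height=128,
        mean_depths=(39.0, 57.0, 83.0),
        curvature_amplitude=4.0,
        curvature_smoothness=50.0,
        attenuation_rate=0.0078,
        shadow_count=3,
        shadow_width=6,
        shadow_attenuation=0.5,
        missing_margin=5,
        seed=seed,
    )


@dataclass
class EndToEndResult:
    report: EvalReport
    log: list
    n_train: int
    n_eval: int


def run_semantic_end_to_end(seed: int = 0, n_participants: int = 100,
                            scans_per_participant: int = 1,
                            split_fraction: float = 0.8,
                            variant: str = "standard",
                            max_epochs: int = 20,
                            batch_size: int = 8,
                            crop: CropRegion = SCALED_CROP,
                            params: PhantomParams | None = None,
                            on_epoch=None,
                            ) -> EndToEndResult:
    """Train a semantic network on phantoms and evaluate the held-out split.

    Returns the per-scan and aggregate evaluation report (Dice per region,
    ME/MAE per boundary, in pixels) for the validation participants, which
    take no part in gradient updates.
    """
    if params is None:
        params = scaled_phantom_params(seed)
    else:
        params = params.with_seed(seed)
    entries = generate_dataset(n_participants, scans_per_participant,
                               split_fraction, params)
    train_entries = [e for e in entries if e.split_tag == "train"]
    eval_entries = [e for e in entries if e.split_tag == "validation"]

    def pairs(split):
        out = []
        for e in split:
            zeroed = zero_missing_columns(e.scan, e.boundaries)
            mask = boundaries_to_area_mask(e.boundaries, e.scan.height)
            out.append((zeroed.pixels, mask))
        return out

    model = build_semantic_model(SemanticModelConfig(variant=variant, seed=seed))
    tconf = TrainConfig(max_epochs=max_epochs, batch_size=batch_size, seed=seed)
    model, log = train_semantic_model(model, pairs(train_entries),
                                      pairs(eval_entries), tconf,
                                      on_epoch=on_epoch)
    logger.info("trained %s variant: best val Dice %.2f%%", variant,
                max(rec.val_metric for rec in log))

    reports = []
    for e in eval_entries:
        pred = segment_scan(model, "semantic", e.scan)
        reports.append(ScanReport.from_boundaries(
            e.scan.identifier, pred, e.boundaries, e.scan.height, crop))
    return EndToEndResult(report=aggregate(reports, crop), log=log,
                          n_train=len(train_entries), n_eval=len(eval_entries))
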