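"""Generate a phantom B-scan and a participant-disjoint dataset.

Prints the dataset counts of the study protocol (50 participants x 6
scans, 80/20 participant split -> 240 training / 60 validation B-scans;
49 further participants -> 294 evaluation B-scans) and basic properties
of one rendered scan.
"""

import numpy as np

from chorioseg import PhantomParams, generate_dataset, generate_scan

params = PhantomParams.scaled_to(width=256, height=128, seed=0)
scan, boundaries = generate_scan(params)
print(f"rendered phantom: {scan.height} x {scan.width} px, "
      f"intensities [{scan.pixels.min():.0f}, {scan.pixels.max():.0f}]")
ok = boundaries.present_mask()
print(f"annotated columns: {ok.sum()} of {scan.width} "
      f"(gaps only near the lateral edges)")
print(f"ordering ILM < RPE < CSI holds everywhere: "
      f"{bool(((boundaries.ilm < boundaries.rpe) & (boundaries.rpe < boundaries.csi))[ok].all())}")

# the study's dataset protocol, on small phantoms for speed
small = PhantomParams.scaled_to(width=64, height=48, seed=0)
set_a = generate_dataset(50, 6, 0.8, small)
set_b = generate_dataset(49, 6, None, small.with_seed(1))
tags = [e.split_tag for e in set_a]
print(f"set A: {len(set_a)} scans -> {tags.count('train')} train / "
      f"{tags.count('validation')} validation (split by participant)")
print(f"set B: {len(set_b)} evaluation scans")
train_p = {e.participant_id for e in set_a if e.split_tag == "train"}
val_p = {e.participant_id for e in set_a if e.split_tag == "validation"}
print(f"participant overlap between splits: {len(train_p & val_p)}")
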