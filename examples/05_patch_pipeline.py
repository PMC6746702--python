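"""Patch-based pixel classification on one phantom: sampling to delineation.

Samples class-balanced boundary/background patches from a noise-free
phantom, trains the small Cifar-style CNN briefly, densely classifies the
crop region into per-boundary probability maps and runs the graph search.
"""

import numpy as np

from chorioseg import (CropRegion, PatchSpec, PhantomParams, generate_scan,
                       sample_training_patches, segment_scan)
from chorioseg.nets import (PatchModelConfig, TrainConfig, build_patch_model,
                            train_patch_classifier)
from chorioseg.patchgen import PATCH_CLASSES

params = PhantomParams(width=96, height=48, mean_depths=(14.0, 24.0, 36.0),
                       curvature_amplitude=2.0, curvature_smoothness=30.0,
                       speckle_level=0.05, attenuation_rate=0.0,
                       shadow_count=0, missing_margin=0, seed=0)
scan, bounds = generate_scan(params)
crop = CropRegion(8, 8)
spec = PatchSpec(16, 16)

rng = np.random.default_rng(0)
patches = sample_training_patches(scan, bounds, spec, crop, rng)
x = np.stack([p.pixels for p in patches])
y = np.array([PATCH_CLASSES.index(p.label) for p in patches])
counts = {c: int((y == i).sum()) for i, c in enumerate(PATCH_CLASSES)}
print(f"sampled {len(patches)} patches, per class: {counts}")

model = build_patch_model(PatchModelConfig("cifar_cnn", 16, 16, seed=0))
model, log = train_patch_classifier(model, x, y, x, y,
                                    TrainConfig(max_epochs=25, batch_size=32,
                                                seed=0))
print(f"best patch-classification accuracy: "
      f"{max(r.val_metric for r in log):.3f}")

pred = segment_scan(model, "patch", scan, spec, crop)
cols = crop.columns(scan.width)
for name in ("ilm", "rpe", "csi"):
    mae = np.abs(pred[name][cols] - bounds[name][cols]).mean()
    print(f"  {name.upper():3s} MAE on this scan: {mae:.2f} px")
print("Near-zero errors show the dense-classification + graph-search "
      "chain localises the boundaries it was trained on.")
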