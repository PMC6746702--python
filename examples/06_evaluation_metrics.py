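"""Evaluation metrics: post-segmentation Dice, ME/MAE, physical scales.

Constructs a truth and a deliberately shifted prediction, then prints the
quantities an evaluation table reports: Dice overlap percentage for the
four regions, mean (signed) and mean absolute boundary errors in pixels,
and the physical extent of a study-format scan.
"""

import numpy as np

from chorioseg import (CropRegion, boundary_errors, dice_all_regions,
                       pixels_to_mm)
from chorioseg.core import BoundarySet

w = 40
truth = BoundarySet(np.full(w, 10.0), np.full(w, 20.0), np.full(w, 30.0))
pred = BoundarySet(truth.ilm + 1.0, truth.rpe - 0.5, truth.csi + 5.0)
crop = CropRegion(0, 0)

print("Dice overlap (%) by region, prediction vs truth:")
for region, value in dice_all_regions(pred, truth, 45, crop).items():
    print(f"  {region:9s} {value:6.2f}")
print("boundary errors (px):")
for name, (me, mae) in boundary_errors(pred, truth, crop).items():
    print(f"  {name.upper():3s}  ME {me:+5.2f} (positive = predicted deeper)"
          f"   MAE {mae:5.2f}")
print(f"study scan extent: {pixels_to_mm(1536, 5.7):.1f} mm wide x "
      f"{pixels_to_mm(496, 3.9):.1f} mm deep")
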