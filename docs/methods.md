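# Methods

This note documents the models, the synthetic data, and the numerical
conventions the package commits to, in enough detail to reimplement them.

## Problem setting

A chorio-retinal OCT B-scan is a grayscale cross-section (here
row-by-column, top-left origin, intensities in [0, 255]) in which three
boundaries are sought per column: the ILM (vitreous→retina), the outer RPE
boundary (retina→choroid) and the CSI (choroid→sclera).  A boundary value
is the real-valued row index of the first pixel of the deeper region; a
column may lack annotations.  The study geometry is 1536×496 px at
5.7 µm/px horizontally and 3.9 µm/px vertically (≈ 8.8 × 1.9 mm).

## Phantom generator

Real training data for this problem is clinical and private, so every
learnable stage runs on phantoms built to exercise the same failure modes:

* **Boundaries** — per boundary, a sum of 2–4 random-phase sinusoids with
  wavelengths at least the `curvature_smoothness` correlation length,
  scaled to `curvature_amplitude` and added to the boundary's mean depth.
  Ordering is enforced by clamping each deeper boundary ≥ 2 px below the
  one above; the clamp makes the anatomical invariant ILM < RPE < CSI
  hold by construction rather than by rejection sampling.
* **Rendering** — each pixel takes its region's mean intensity
  (defaults 10 / 150 / 110 / 80 for vitreous / retina / choroid / sclera:
  dark vitreous, bright retina, a choroid slightly brighter than the
  sclera so the CSI has weak but nonzero contrast), multiplied by
  `exp(−attenuation_rate · row)` depth decay, by unit-mean gamma speckle
  with standard deviation `speckle_level` (the standard multiplicative
  OCT speckle approximation), and by `shadow_attenuation` below the ILM
  inside randomly placed vertical bands (vessel shadows); clipped to
  [0, 255].
* **Missing annotations** — only within `missing_margin` columns of the
  lateral edges, each boundary dropped independently with probability 0.5,
  mimicking edge shadows in clinical exports.
* **Datasets** — participants receive depth-jittered (±8 %) copies of the
  base parameters; train/validation splits are by participant
  (`round(f·n)` training participants), so no participant straddles a
  split.  All randomness flows from a single integer seed; identical
  parameters give byte-identical scans.

What the phantoms do **not** model: real choroidal vasculature texture,
drusen or pathology, the optic nerve head, instrument noise statistics
beyond first order, or any Beer–Lambert coupling between region
reflectivity and attenuation.  Passing tests on phantoms demonstrates the
pipeline's mechanics (learnability, delineation optimality, metric
correctness), not clinical accuracy.

## Attenuation compensation

`contrast_enhance` implements the standard attenuation-compensation
family: `E(i,j) = I(i,j)^n / (2 Σ_{k≥i} I(k,j)^n + ε)` with exponent
`n = 2` by default and stabiliser `ε = 1e−8`, rescaled to [0, 255] by the
per-image maximum.  The tail sum includes the current row.  Both `n` and
`ε` are configurable because the literature contains minor dialects of
this operator.  Two caveats are inherent to the operator: the last rows of
any finite column diverge (the tail sum vanishes), and band-mean
comparisons are only meaningful away from the image bottom — the
choroid/sclera contrast-gain property is therefore stated over
matched-thickness bands at the CSI with ample scleral depth below.

## Patch-based method

Patches of height×width 32×32, 64×32, 64×64 or 128×32 are anchored with
the target pixel at position (h/2 − 1, w/2 − 1) — one pixel above-left of
centre — and labelled ILM/RPE/CSI when anchored on a (half-up-rounded)
boundary row, else background (BG).  Training samples, per fully
annotated column inside the crop region, one patch per boundary plus one
BG patch at a uniform row at least 2 rows away from every boundary
(a 1 px exclusion band avoids rounding-ambiguous labels); the four classes
are exactly balanced.  Out-of-image content is mirror padded, avoiding the
dark-border bias zero padding would give dense classification.  At
inference every crop-region pixel is classified; the class-b probability
at each anchor forms boundary map b (columns outside the crop are zero).

Exact layer tables for the three classifiers are not fixed by the source
material; the package follows the cited architecture families — Cifar
CNN: three 5×5 conv+maxpool stages (32/32/64) and two fully connected
stages; Complex CNN: five 3×3 conv stages (32/32/64/64/128) with three
poolings and a 128-unit head; ReNet RNN: bidirectional tanh sweeps over
non-overlapping 2×2 tiles, vertical then horizontal, 32 filters per
direction, light dropout, linear softmax head.  The deliberate structural
ordering — RNN fewest parameters, Complex CNN most — is asserted in tests.
No dropout in the CNNs.

## Semantic method

U-Net with `n_pool = 4` and `base_filters = 8` (8→16→32→64→128), two
(3×3 conv → batch-norm → ReLU) stages per block, zero-padded convolutions
so sizes are preserved, nearest-neighbour upsampling followed by a 3×3
conv and skip concatenation in the decoder, 50 % dropout at the
bottleneck output, 1×1 conv to 4 area classes.  Variants: *residual*
(identity shortcut across each block, 1×1 projection on channel change),
*rnn_bottleneck* (bottleneck convolutions replaced by vertical then
horizontal bidirectional recurrent sweeps), *cSE* (global-pool →
two-layer bottleneck → sigmoid channel gains), *sSE* (1×1 conv → sigmoid
spatial gate), *scSE* (elementwise max of the two; `add` available as a
config switch since the literature uses both), and *combined*
(residual + RNN bottleneck + scSE).

Targets are area masks: vitreous above the ILM, retina, choroid, sclera
below the CSI, with real boundary rows rounded half-up; columns missing
any boundary are set entirely to vitreous and the same image columns are
zeroed.  Augmentation: a 50 % horizontal flip of image and mask together,
drawn per image per epoch.

## Training protocol

Adam with α = 1e−3, β₁ = 0.9, β₂ = 0.999, ε = 1e−8; no early stopping, no
learning-rate schedule, no transfer learning; weights start from small
He-scaled normals.  Patch classifiers minimise cross-entropy; semantic
networks minimise cross-entropy plus the Dice-overlap loss

`L_Dice = 1 − mean_c (2 Σ p_c g_c + s) / (Σ p_c² + Σ g_c² + s)`,  s = 1,

with equal class weights.  The squared-denominator (V-Net) form is the
default; `squared=False` selects the plain-sum variant.  Training runs a
fixed number of epochs and returns the checkpoint with the highest
validation metric (patch accuracy / mean validation Dice of the argmax
segmentation) — an automatable stand-in for manual convergence inspection.
Runs are bit-reproducible given the seed.

The networks execute on a package-local NumPy reverse-mode autodiff engine
(im2col convolutions, pooling/upsampling, batch-norm with running
statistics, recurrent sweeps, fused softmax/cross-entropy); every operator
is validated against central finite differences in the test suite.

## Boundary delineation

Boundary maps from the semantic method are the positive part of the
vertical 3×3 Sobel response of the deeper region's probability plane,
rescaled to [0, 1].  A probability step between rows b−1 and b excites a
symmetric two-row Sobel plateau whose argmax parity is decided by noise;
the response is therefore aligned by summing each adjacent row pair onto
the lower row, making a crisp step peak uniquely at b — the first row of
the deeper region, i.e. the boundary-row convention.  Maps from the patch
method need no alignment (the classifier is trained on anchors already at
the convention).

The graph has one vertex per pixel, edges to the right/diagonal-right
neighbours with weight `2 − (P_s + P_d) + 1e−5`, and a probability-1
auxiliary column on each side (vertical top-to-bottom edges inside,
full three-row fans into/out of the adjacent real column) so the path may
enter and exit at any row at negligible cost.  Dijkstra runs from the
top-left to the bottom-right auxiliary vertex; exact cost ties prefer the
smaller predecessor row, making results deterministic.  The three
boundaries are searched independently on full-size maps; an ordering
violation in the result is logged as a warning, never raised.  A
dynamic-programming oracle in the tests must agree exactly on random
instances.

## Evaluation

Dice is always computed post-segmentation — region masks are rebuilt from
the predicted and true boundary positions over the crop columns
(defaults 100 left / 250 right at full width, scaled proportionally for
smaller phantoms) — so Dice measures delineation quality, not raw network
output.  ME = mean(pred − truth) per boundary (positive = predicted
deeper; the sign convention is this package's choice), MAE = mean
absolute error, both in pixels against the un-rounded truth.  Aggregates
report the mean and the sample (n−1) standard deviation of per-scan
values; a single scan reports std 0 with a logged caveat.  The
empty-empty Dice case is defined as 100.

## Scaled end-to-end protocol

The full-scale experiment (hundreds of 1536×496 scans, dozens-of-epoch
training) is reproduced structurally at a desk scale chosen so a complete
run takes minutes on one CPU: 100 participants × 1 phantom of 128×256 px
(depths, curvature, attenuation, shadows and margins scaled from the
full-size defaults), 80/20 participant split, the standard U-Net trained
with the protocol above and evaluated on the 20 held-out phantoms over
the proportionally scaled crop (17, 42).  The acceptance bar for this
synthetic task — ILM and RPE MAE ≤ 1.5 px, CSI MAE ≤ 3.5 px — encodes the
expected difficulty ordering (retinal boundaries sharp, CSI weakly
contrasted), not any clinical figure.

## Known limitations

* The autodiff engine is single-threaded NumPy: wall-clock costs restrict
  experiments to small images and few epochs; no GPU path exists.
* Patch-based dense classification is O(pixels × patch area) and is the
  slow path, as expected for this method class.
* Dijkstra on very large maps (full 1536×496) takes seconds per boundary;
  the auxiliary-column `w_min` hops make degenerate all-equal maps drift
  toward deeper exit rows by design of the edge weights.
* Phantom realism limits: see the generator section; results on phantoms
  bound nothing about clinical data.
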