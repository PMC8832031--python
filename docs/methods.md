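# Methods

## The model

`attr2unet` implements a five-level encoder–decoder segmentation network for
2-D grayscale slices with three mechanisms layered onto the U-Net skeleton:

**Spatial attention gates on skip connections.** At decoder level *i* the
encoder features `x_e` are re-weighted before fusion by a per-pixel soft
coefficient map

```
lambda = W_e * x_e + W_d * x_d + b_lambda      (1x1 convolutions)
mu     = psi * ReLU(lambda) + b_mu             (1x1 convolution to 1 channel)
alpha  = sigmoid(mu),   gated = alpha ⊙ x_e
```

where `x_d` is the decoder guidance at the same resolution (the up-conv
output). Coefficients lie strictly in (0, 1); the gate can only attenuate,
never amplify, encoder features. The intermediate width is half the encoder
channel count (floored at 1).

**Recurrent convolutional layers (RCL).** Each conv layer unrolls over `t`
discrete time steps. The feedforward drive `W_f * x + b` is constant across
steps; from the second step onward the layer adds a recurrent transform
`W_r * O(τ−1)` of its previous output. Every step is conv → batch norm →
ReLU. `t` counts total conv passes, so `t = 1` is a plain conv layer. The
first step uses the feedforward term only (the recurrent state starts at
zero). Feedforward/recurrent weights and the batch-norm state are shared
across steps; a `per_step_bn` flag exposes the un-tied alternative, since
the step-indexed notation of the defining recurrences is ambiguous on this
point.

**Residual connections.** Each block (RRCB) is a 1x1 channel-matching
convolution followed by two RCLs, with the block input added back:
`out = alpha_mod * shortcut + body(shortcut)`. The modulating scalar
`alpha_mod` defaults to 1 (plain residual addition). The closed-form
expansion of stacked residual layers (`unrolled_residual_input`) exists
purely as a verification utility: the telescoped product/sum form must agree
with iterating the one-step recursion, and tests enforce this.

Architecture: 5 encoder blocks with 2x2 max pooling between levels (channel
widths `b, 2b, 4b, 8b, 16b`), 4 decoder blocks each preceded by an up-conv
(2x nearest-neighbour upsample + 3x3 conv + BN + ReLU) and skip fusion
(attention-gated concatenation, or plain concatenation when attention is
off), then a 1x1 conv + sigmoid head. Inputs must be divisible by 16 in both
spatial dimensions. Dropout is applied after the two deepest encoder blocks.

## Numerical substrate

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine on numpy (`attr2unet.nn`) providing exactly the
operations the network needs (stride-1 convolution via windowed einsum
contractions, batch norm, 2x2 max pooling, nearest upsampling, channel
concatenation, dropout, fused binary cross-entropy) plus Adam. Gradients of
every operation are verified against central finite differences in the test
suite, end-to-end through the assembled network.

Numerical choices:

* Batch-norm epsilon 1e-5, momentum 0.1, biased variance for normalization,
  unbiased for the running estimate. Running statistics start undefined;
  eval-mode use before any training batch raises.
* Max-pool ties break toward the first maximal element (stable argmax), so
  gradients route to exactly one pixel per window.
* Output probabilities are clamped to [1e-6, 1 − 1e-6]: the head sigmoid
  saturates to exactly 0/1 at float32 precision, and the clamp keeps the
  probability-map contract (open interval) and the BCE loss finite.
* BCE predictions are clipped at 1e-7; the clip region contributes zero
  gradient.
* Weight init: fan-in-scaled normal for convolutions, gamma = 1 / beta = 0
  for batch norm, all drawn from one seeded generator so two builds with the
  same seed are parameter-identical.
* Training is float32; component tests run the same code in float64 when
  comparing against scalar oracles at 1e-6.

## Training protocol

Adam with beta1 = 0.9, beta2 = 0.999, L2 weight decay 1e-5, initial learning
rate 1e-3 halved after 5 epochs without validation improvement (the decay
schedule is a package choice; only "a decay strategy" is prescribed).
Loss is mean per-pixel binary cross-entropy. After every epoch the
validation mean Dice coefficient at threshold 0.5 is computed and the
best-epoch parameters (including batch-norm statistics) are restored at the
end. Batch size defaults to 8. Training is bit-reproducible for a fixed seed
in single-threaded CPU execution; shuffling, dropout and initialization all
derive from the run seed.

## Preprocessing

* Z-score normalization uses pooled-pixel statistics computed on the
  training split only and applied to all splits — this avoids test-set
  leakage while matching the "all original pixels" convention as closely as
  a leak-free protocol can. A per-image mode is provided as an option; it
  additionally removes per-acquisition brightness/contrast offsets.
* ROI cropping takes the mask bounding box plus a margin, clipped to the
  image; empty-mask slices are rejected (the dataset convention keeps only
  lesion-containing slices). Windows are half-open, row-major, 0-based.
* Resizing: bilinear for images, nearest for masks with re-binarization at
  0.5.
* The 80/10/10 split floors the train and validation counts and gives the
  remainder to test — the only rounding convention that reproduces a
  478-image test set from a 4,775-image cohort.
* Patient-wise k-fold assignment shuffles the distinct patients with the
  run seed and deals them round-robin, so fold sizes differ by at most one
  patient (93 patients, k = 5 → sizes {19, 19, 19, 18, 18}) and no patient
  contributes slices to two folds.
* Augmentation: horizontal mirroring, rotations drawn from ±5°/±10°, and
  mild affine transforms (scale 0.9–1.1, shear ≤ 5°), identical for image
  and mask. Magnitudes are configurable; the defaults preserve anatomical
  plausibility. Because the published preprocessing augments before
  splitting (which lets transformed copies of one slice cross the
  train/test boundary), this package intentionally augments after the
  split, training data only; the original-to-augmented ratio is an explicit
  target count rather than a guessed recipe.

## The phantom generator

Real head-and-neck tumor MRI is rarely shareable, so the package ships a
generator that reproduces the statistical difficulties of the task, not its
anatomy. Each 2-D slice contains:

* a head-shaped ellipse with a smoothed random background field and
  concentric "anatomy" rings;
* one connected star-convex lesion whose area fraction is drawn from
  0.002–0.06 of the image, with radial-harmonic shape irregularity
  (amplitude 0.3 by default; 0 gives an exact ellipse) and a laterality
  bias (default 0.7) placing it off-centre, mirroring the clinical
  observation that lesions often occupy one side;
* distractor structures (thin arcs, small elongated blobs) drawn in the
  lesion's intensity band but excluded from the mask — these defeat plain
  intensity thresholding (Otsu segmentation scores mean DSC ≈ 0.1–0.3 on
  default cohorts);
* a per-patient "scanner profile": an affine brightness/contrast transform
  plus additive noise, so intensity statistics cluster by patient the way
  acquisition differences make them cluster across real scanners.

Everything derives from one root seed via seed-sequence spawning per
(patient, slice), so cohorts are exactly reproducible. Output is quantized
to 8 bits by default so fixtures round-trip through PNG losslessly.

What the phantoms do **not** model: 3-D anatomy and inter-slice coherence,
MR physics (bias fields, partial volume, motion), multi-focal or infiltrative
lesion topology, and annotation noise. A model that segments these phantoms
well has demonstrated that the implementation can learn shape-plus-intensity
structure under scanner variation — not that it reaches any particular
accuracy on clinical data.

## Scaled-down benchmark

The reference experiment used by the acceptance script and the slow
acceptance test trains the reduced network — base width 4, t = 2 — on a
cohort of 20 patients of 64x64 slices (6–14 slices each, ~200 slices),
split 80/10/10, training split augmented 3x, 30 epochs, batch 8, lr 1e-3,
weight decay 1e-5. These problem sizes are the package's CPU-scale
reference configuration; the same harness runs the full-width model
unchanged. The benchmark compares the full-mechanism variant against the
skeleton under one shared seed and split.

Three benchmark-specific option choices, each exposed as a regular
configuration flag:

* `per_step_bn = True`. With batch-norm state shared across recurrence
  steps, the running statistics average two different step distributions
  and match neither at eval time; at t = 2 this measurably depresses
  eval-mode accuracy. Per-step batch norm gives each step its own
  statistics and removes the mismatch. The package default keeps the tied
  variant (the defining recurrences index parameters by step without
  stating whether they are shared).
* `norm_scope = "per_image"`. Phantom cohorts carry per-patient scanner
  profiles; per-image z-scoring removes exactly that nuisance variation,
  which a width-4 model otherwise spends capacity absorbing. Dataset-scope
  normalization remains the package default.
* `dropout_rate = 0`. Heavy elementwise dropout at the two deepest blocks
  destabilizes the width-4 model (validation accuracy collapses while
  training loss keeps falling); dropout is intended for the full-width
  regime.

## Ablation variants

Nine named configurations toggle the three mechanisms and normalization:
`Att+Rec+Res` (full), `Att+Rec`, `Att+Res`, `Rec+Res`, `Only Att`,
`Only Rec`, `Only Res`, `Skeleton`, and `Without Norm` (all mechanisms, no
z-score). With recurrence off, layers collapse to single conv passes and no
recurrent weights are allocated; with recurrence on, `W_r` exists for every
t (including t = 1, where it is unused), so the t-sweep compares models of
identical parameter count — recurrence spends computation, not parameters.

## Evaluation conventions

Metrics (Dice, Jaccard, precision, specificity, sensitivity) are computed
per slice from confusion counts and averaged (mean ± sample std); a pooled
mode exists but is not the default. Degenerate slices: empty truth and empty
prediction count as perfect; empty truth with a non-empty prediction counts
as zero. The PR curve pools pixels across slices, evaluates
precision/recall at every distinct score, anchors recall 0 at the first
achievable precision and integrates by trapezoid over recall. Fold summaries
use the sample (n−1) standard deviation. The radar-percentage transform maps
0.5 → 0% and the per-metric maximum → 100%. Kruskal–Wallis is delegated to
scipy (with the all-identical-values case resolved to H = 0, p = 1) and is
cross-checked against a from-scratch rank computation in the tests.

## Known limitations

* Single-channel 2-D inputs only; no 3-D context.
* CPU-scale: the numpy substrate is single-threaded-deterministic but far
  slower than a GPU framework; full-width (base 64) training at 256x256 is
  out of reach on one CPU and the defaults for CPU experiments are reduced
  accordingly.
* The benchmark's slice-level split means patients can span train and test;
  the patient-wise cross-validation harness is the leakage-free protocol.
* The Kruskal–Wallis comparison assumes independent per-slice scores, which
  slices from one patient violate; it is reported as a descriptive statistic.
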