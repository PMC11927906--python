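# Methods

## Scope and model

`platescreen` implements a plate-based phenotypic screening pipeline for
neuroinflammation end to end: synthetic image generation, montage
stitching and overlapping cropping, per-channel normalization and
augmentation, crop-level classification, leave-plates-out cross-validation,
the rounded-mean ensemble well verdict, percent-CTL dose-response
quantification, and paired-classifier statistics. The unit of biology is
the well; the unit of confounding is the plate; the unit of prediction is
the crop. Everything above the classifier treats the classifier as a
contract (`fit`/`predict_proba` on aligned crops and labels), so the
reference backend can be swapped for a CNN without touching the pipeline.

## Synthetic microscopy

The simulator emulates the features of the real assay that the pipeline's
logic depends on, and only those:

* **Severity-graded morphology.** A scalar severity in [0, 1] interpolates
  linearly between class anchors (class 0 → 0.0 … class 5 → 1.0; the LPS
  ladder is ordinal, so linear interpolation is the least-commitment
  choice). Microglia are disc somas with radiating random-walk processes:
  soma radius grows (4 → 9 px at the 200-px reference tile) and process
  count (5 → 0) and length (32 → 6 px) shrink with severity — the
  ramified→ameboid transition. Neurons are small somas with shallow
  binary-tree neurites whose count (4 → 1) and length (45 → 12 px) shrink
  with severity — neurite retraction. Nuclei are severity-independent
  filled ellipses. All counts are Poisson per tile (nuclei 14, neurons 6,
  microglia 5 per 200-px tile); all lengths scale with tile size. These
  numerics are simulator choices tuned for visual plausibility at
  10×-like density — no quantitative morphology values exist to validate
  them against, which is the main respect in which passing tests bound
  claims about real data.
* **Plate batch effects.** One effect per plate, applied to every tile:
  per-channel gain ~ LogNormal(0, σ) and offset ~ Uniform(0, max), optional
  Gaussian blur, as `clip(gain·pixel + offset)`. σ = 0.25 (mild) by
  default; the batch-effect-mitigation experiments use σ = 0.5, offset up
  to 0.15. Log-normal gain + uniform offset matches common microscopy
  staining/exposure variability; the functional form is configurable.
* **Compound rescue.** Effective severity =
  base_severity · (1 − max_rescue · d^h/(d^h + EC50^h)). Rescue(0) = 0 and
  rescue is monotone in dose by construction.
* **Seeding.** Well geometry derives from a geometry seed, the plate
  effect from a separate plate seed, so the pure batch-effect contrast
  (same cells, different plate) is constructible. Identical inputs are
  bit-identical outputs.

Not emulated: point-spread functions, chromatic aberration, astrocytes,
3-D stacks, cell–cell contact, and focus drift. Tests passing on this
simulator demonstrate the pipeline's logic (leakage-free folds, correct
aggregation arithmetic, direction of batch-effect mitigation), not
classifier performance on real microscopy.

## Crop geometry

Stitching places tile (r, c) at origin r·(t−o) with o = round(overlap·t),
averaging overlap strips; default overlap 0. The 4×4 crop grid uses stride
s = floor((side − crop)/3), which reproduces both the 4×4 count and
adjacent-crop overlap with no free parameter. When (side − crop) is not
divisible by 3 a residual border of at most 2 px at the right/bottom edge
falls outside all crops; the coverage test bounds this explicitly. The
bottom-right cell is discarded by default (configurable), leaving 15 crops
indexed row-major over kept cells. Coordinates are 0-based, half-open.

## Preprocessing

Channel statistics (mean, sd on the 0–1 scale) are pooled over training
pixels only; normalization is (p − µ·255)/(σ·255). Per-plate pixel sums are
accumulated during feature extraction, so exact per-fold statistics are
obtained by pooling the fold's training plates without re-rendering — the
default is therefore per-fold recomputation (no leakage), with global
statistics available by pooling all plates.

Solarization defaults to the classic invert-above-threshold form
(bright pixels turn dark), because the indicator-product form `I·[I>0.95]`
contradicts that described behaviour; the literal mask is kept as a
selectable mode and both are tested. Multiplicative noise uses
u ~ Uniform(−0.2, 0.2) (bounded, mean-adjustable; the distribution is
otherwise unconstrained). Augmentation applies exactly one operator to a
seeded `round(0.10·N)` sample without replacement; copies carry an
`augmented` flag and are excluded from every validation and test split.
The exotic operators (motion blur, optical distortion, sun flare, snow,
sharpen, emboss) use standard definitions at conservative magnitudes.

## Reference classifier

Each crop maps to 22 features: per channel, mean and sd of intensity,
foreground fraction (Otsu threshold with a constant-channel fallback and
an 8-px small-object filter), object count, mean object area, mean
circularity 4πA/P², and skeleton length per object; plus the
microglia/neuron foreground ratio. Skeletons are computed on a canonical
representative of the mask under the dihedral group, making the feature —
and hence the whole vector — exactly invariant to flips and 90°
rotations. Training is multinomial logistic regression on standardized
features (statistics from the training fold only), seeded mini-batch
gradient descent with batch size 8, initial learning rate 0.1 decayed
×0.25 every 5 epochs, 20 epochs, L2 1e−4, zero initialization. Everything
is deterministic under a fixed seed. The initial rate and epoch count are
this package's defaults; they matter little at 22 dimensions.

Binary screening models are trained on control vs the mildest LPS class
only (0.005 µg/ml — the reversible-inflammation regime a compound can
rescue), with label 1 = control.

## Aggregation rules and tie-breaks

* Ensemble well verdict: mean of the 15×K binary matrix; CTL iff
  mean ≥ 0.5. Round-half-up is fixed (banker's rounding would make the
  exact-tie verdict representation-dependent).
* Per-crop ensemble verdict (for percent-CTL): model-mean ≥ 0.5, then
  crops are counted — the readout counts crops classified as control, not
  well-mean scores.
* Multiclass well verdict: round-half-up of the mean crop label
  (ordinal-aware default); majority vote with ties to the lower class is
  selectable. Neither rule is canonical; both are provided.
* Macro F1: a class with TP = FN = FP = 0 contributes 0.
* McNemar continuity correction clamps (|a−b|−1)² at 0 for |a−b| < 1.
  With and without correction give 27.27 and 29.12 on a = 32, b = 1; both
  variants are exposed because both conventions circulate, and every
  report states which was used.

## Cross-validation

Plates are shuffled (seeded) and dealt into groups as evenly as possible:
7 plates → (2, 2, 2, 1). Validation excludes augmented copies; training
splits must contain every class or the fold aborts with a diagnostic.
Fold metrics retain image-wise and well-wise confusion matrices.

## Experiment scales

The canned experiments (`platescreen.experiments`) run at deliberately
reduced scale so a full study is minutes on one CPU: 120-px tiles, 128-px
crops, 4 plates × (2 classes × 4 wells) for the binary batch-effect and
dose-response studies (leave-one-plate-out, 10 seeds), and 4 plates ×
(6 classes × 2 wells) for severity recovery. The dataset-arithmetic checks
use the full design (7 plates × 6 classes × 5 wells, 200-px tiles,
256-px crops). A seed whose dose curve saturates at a constant level has
no rank information; its Spearman ρ is recorded as NaN and excluded from
the mean.

## Known limitations

* The reference classifier's absolute F1 is far below a fine-tuned CNN's;
  only directions and orderings (ensemble ≥ median single model, severity
  rank recovery, dose monotonicity) are meaningful claims at this scale.
* The simulator's severity signal is monotone by construction, so
  correlation-based recovery tests cannot fail for biological reasons,
  only for pipeline defects — that is their purpose.
* Percent-CTL saturates near 0/100% for strongly separable settings,
  flattening dose curves at the ends of the ladder.
* The asymptotic McNemar χ² is unreliable for a + b ≲ 10; the exact
  binomial variant is out of scope.
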