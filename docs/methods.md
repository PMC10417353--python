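# Methods

`gliotrack` re-implements, at desk scale, a post-operative glioma imaging
pipeline: radiotherapy target segmentation from two MRI sequences, removal
of the resection cavity from the high-dose target, and automated BT-RADS
scoring of longitudinal lesion volumes. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The problem

After glioblastoma resection, radiotherapy is planned on two gross tumor
volumes: **GTV1**, the T2w/FLAIR hyperintense region including the cavity
and blood products (lower dose), and **GTV2**, the contrast-enhancing
lesion plus cavity on CE-T1w (higher dose); GTV1 ⊇ GTV2 by construction.
Post-surgical morphology — a dark cavity, a thin enhancing rim, blood
products — is exactly what pre-operative segmentation models were never
trained on, which motivates a dedicated pipeline. For follow-up, the
enhancing-lesion volume (cavity removed) and the FLAIR lesion volume are
tracked across visits and converted into BT-RADS scores by percent-change
rules.

## Synthetic phantoms (`phantoms`)

No public dataset exists for this task, so every stage is exercised on
synthetic phantoms whose ground truth is *analytic*:

* **Geometry.** Concentric spheres: cavity (radius `cavity_radius_mm`,
  default 10 mm), enhancing rim shell (`rim_thickness_mm`, 3 mm), edema
  sphere (`edema_radius_mm`, 22 mm), plus an optional residual enhancing
  nodule placed tangent to the outer rim surface (`nodule_radius_mm`,
  4 mm). Tangency keeps the nodule disjoint from the rim sphere, so
  GTV2 volume = shell-sphere + nodule-sphere in closed form; when a nodule
  is present the generator requires `edema >= cavity + rim + 2*nodule` so
  GTV2 stays nested in GTV1. The brain is a sphere at 78% of the half
  field of view, the skull a 4 mm shell outside it (so the with-skull
  input channel is meaningful); `abut_skull=True` moves the cavity tangent
  to the inner skull surface. Spheres were chosen over realistic lobed
  shapes because they make every volumetric check quantitative.
* **Intensities.** Arbitrary units, not calibrated MRI signal: per-tissue
  means (cavity 20, brain 100, edema 160 on FLAIR, enhancement 180 on
  CE-T1w, blood 200 on FLAIR), a Gaussian point-spread blur
  (`psf_sigma_mm`, default 1 mm) emulating partial-volume transitions, and
  additive Gaussian noise with standard deviation `noise_sd` × brain mean
  (default 0.05) inside the head only. The blur matters: a four-class Otsu
  step is only meaningful when the histogram has intermediate
  partial-volume values between cavity and enhancement; with
  `psf_sigma_mm=0` the generator emits exactly piecewise-constant tissue
  means (used by the zero-noise exactness tests). Blood product is a bright
  FLAIR crescent hugging the cavity with no separate mask — it is never
  scored separately.
* **Longitudinal series.** A `TrajectorySpec` prescribes per-visit volume
  multipliers relative to baseline. The FLAIR (GTV1) multiplier rescales
  the edema radius cubically. The enhancing multiplier targets the total
  enhancing compartment (rim + nodule): the rim is held fixed and the
  nodule radius is solved in closed form; a target at or below the rim
  volume removes the nodule. When a large nodule would pierce the edema
  surface, the edema radius is grown to preserve nesting and a warning is
  emitted if this overshoots the requested GTV1 multiplier by more than 5%.
* **What a green test does not establish.** Phantoms have spherical
  lesions, piecewise-constant tissue, Gaussian noise, no bias field,
  no registration error, and no anatomy (ventricles, vessels) that real
  models confuse with cavities. Segmentation accuracy on phantoms says the
  training/inference machinery works, not that the architecture reaches
  clinical accuracy.

Defaults: 64³ voxels at 2 mm for fast tests; full-size (256, 256, 160)
generation is supported but not default. Lesion-size defaults are chosen
for testability (the source cohort's size distribution is not published).

## Preprocessing (`preprocess`)

Inputs are assumed registered onto the CE-T1w grid (registration
estimation is out of scope). The pipeline is resample → normalize:
resampling to a common grid (default (256, 256, 160)) preserves the
physical field of view by rescaling spacing; images interpolate
trilinearly, masks nearest-neighbour. Normalization is zero-mean /
unit-variance over *nonzero* voxels only, population (n) denominator,
leaving background exactly zero. Skull-stripped channels are normalized
after masking (statistics over brain only); the with-skull channel over
the whole head — each channel is internally standardized.

Channel recipes: GTV1 → (FLAIR stripped, CE-T1w stripped, FLAIR
with-skull); GTV2 → (CE-T1w stripped, FLAIR stripped, CE-T1w with-skull).
The with-skull channel helps delineate cavities abutting the skull.
Training crops (default (128, 128, 128)) are centred on a uniformly chosen
foreground voxel with probability 0.5, else placed uniformly — a standard
oversampling choice where the source gives none.

## Segmentation model (`model`, `nn`)

A depth-3 3D U-Net: per level two 3×3×3 convolutions (instance norm +
ReLU), 2× max pooling, filters 32→64→128 with 256 at the bottleneck
(configurable; nothing downstream depends on filter counts); decoder with
nearest-neighbour upsampling and skip concatenation; 1×1×1 head with
sigmoid. GTV1 and GTV2 are two independently trained binary models.

Because no deep-learning framework is available in the target environment,
the layers are implemented directly in NumPy with explicit
backpropagation: convolutions are lowered to im2col matrix products (BLAS),
and each layer's backward pass is hand-derived and verified against finite
differences in the test suite. The engine is single-sample, stride-1,
CPU-only — sized for the tens-of-voxels volumes used here, not for
clinical grids.

Training: soft Dice loss `1 − (2Σpt+s)/(Σp+Σt+s)` with smoothing
`s = 1e-5`; Adam (default lr 1e-4, exposed — the desk-scale tests use
1e-3); on-the-fly augmentation applying, each with probability 0.5, a
random axis flip and a random 90°-multiple in-plane rotation (multiples of
90° keep labels exact; the source states "rotation" without angles);
plateau LR scheduler (factor 0.5, patience 5); early stopping when the
best validation Dice is `patience` (default 10) or more epochs old, with
strict improvement and first-occurrence tie-breaking; the
best-validation-Dice checkpoint is returned. "Validation accuracy" is
interpreted as mean validation Dice of predictions binarized at 0.5.
Inference is whole-volume (padded to a multiple of 2^depth) or
sliding-window with probability averaging over overlaps, thresholded at
0.5.

## Evaluation metrics (`metrics`)

Dice `2|A∩B|/(|A|+|B|)` and Jaccard `|A∩B|/|A∪B|` (both 1.0 when both
masks are empty, and related by `J = D/(2−D)`), plus the Hausdorff
distance implemented exactly as defined by the source: *directed*, ground
truth → prediction — the largest distance from a ground-truth voxel to its
nearest predicted voxel — reported in millimetres between voxel centres.
This deliberately differs from the more common symmetric HD95; symmetric
and percentile variants exist as flags. An empty mask yields infinity with
a warning. The implementation (Euclidean distance transform sampled at
ground-truth voxels) is tested to equal O(n²) brute force.

## Cavity removal (`cavity`)

Within the GTV2 mask, CE-T1w intensities are clustered into **four**
classes by multi-level Otsu thresholding (128 histogram bins) and the
lowest-intensity class — the cavity — is removed; classes 2–4 are all
retained. Otsu runs on whatever intensities are supplied (normalized by
default); thresholds are affine-invariant up to binning, so the choice is
immaterial. Class labels are assigned by histogram-bin membership relative
to the optimal cuts (not by comparing raw values against bin-centre
thresholds, which mislabels values inside the threshold's own bin on
coarse histograms). No morphological cleanup is applied by default.
Degenerate intensity distributions return the mask unchanged with a
warning. FLAIR lesion volume for tracking is the full GTV1 volume,
uncorrected. The residual Dice error of cavity removal on phantoms is a
partial-volume effect at the cavity–rim boundary and shrinks with voxel
size; the recovery acceptance check therefore runs at 1 mm isotropic
(clinical resolution).

## BT-RADS scoring (`btrads`)

Percent change is computed against the immediately preceding visit
(baseline-referenced change is not used). A measurability floor
`min_measurable_cc = 0.1` guards the division: a newly measurable lesion
raises a new-lesion flag (treated as unbounded growth), a lesion falling
below the floor a resolved flag, and two unmeasurable volumes count as 0%.

The decision tree, evaluated in order:

1. baseline visit → **0**;
2. FLAIR changed by ≥ 100% **or** enhancing grew ≥ 40% (or new lesion) →
   **4** (recurrence);
3. enhancing grew ≥ 20% or FLAIR grew ≥ 50% → **3**, sub-letter: **c** if
   the previous visit was itself worsened, else **a** within
   `post_rt_window_days = 90` of RT completion, else **b**;
4. one measure down and the other up beyond a ±10% stability band → **3b**
   (mixed findings);
5. both down beyond the band (or resolved) → **1**;
6. otherwise → **2**.

All cutoffs are inclusive ("or greater"). Choices made where the source is
open: the FLAIR recurrence rule reads "changed by 100%" literally, so a
100% shrinkage also fires (an `increase_only` mode is provided); "shortly
after RT" is operationalized as ≤ 90 days, configurable; the
improved-vs-stable split (1 vs 2) uses the ±10% band; the mixed-findings
rule (4) is an addition needed to reproduce the worked example's 3B visit,
whose exact numeric conditions are not published; when 3c and 3a both
apply, 3c wins. Rule 4 intentionally breaks global monotonicity of the
major score in each volume change (leaving the mixed region can move
3b → 2); monotonicity holds, and is property-tested, wherever the held
measure is outside `[stability band, worsened cutoff)`. Missing
`days_since_rt` when 3a would be reachable falls through to 3b with a
warning. Medication metadata is accepted but never alters scores.

## Numerical and degenerate-input conventions

* Population (n) variance everywhere statistics are normalized.
* Masks are validated binary; mixed grids raise `ValidationError`,
  constraint violations `ParameterError`, valid-but-unusable inputs
  `DegenerateInputError`.
* Otsu threshold ties (equal between-class variance) are resolved by the
  underlying scikit-image search order; the test oracle compares attained
  criterion values, not threshold identity.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); training is reproducible run-to-run on one
  device.

## Desk-scale budgets

The test suite trains real networks, scaled to minutes: segmentation
recovery trains base-8 filters on 32³ phantoms (10 train / 4 held-out)
instead of the nominal 20 phantoms at 48³, and the overfit-one-sample
convergence oracle runs at 32³ without augmentation. Accuracy thresholds
are unchanged by the scaling; only volume sizes and cohort counts shrink.

## Known limitations

* The NumPy engine is orders of magnitude slower than a GPU framework and
  is not intended for clinical-size volumes.
* Phantom realism is deliberately limited (see above); no claim about
  test-set Dice on real cohorts is made or reproduced.
* Registration, skull-stripping and bias-field correction are assumed done
  upstream.
* Sub-scores 3a/3b/3c depend only on volumes, timing and the worsened
  chain — not on the clinical/diffusion features a radiologist would also
  weigh.
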