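# gliotrack

Post-surgical brain-tumor segmentation and longitudinal tracking, fully
testable at desk scale on synthetic MRI phantoms.

## The problem

After glioblastoma resection, radiation oncologists contour two gross
tumor volumes on co-registered MRI: **GTV1**, the T2w/FLAIR hyperintense
region including the resection cavity and blood products (lower dose,
50–51 Gy), and **GTV2**, the contrast-enhancing lesion plus cavity on
CE-T1w (higher dose, 60 Gy), with GTV1 ⊇ GTV2. On follow-up, changes in
lesion volumes drive structured response scores (BT-RADS 0–4, with 3a/3b/3c
sub-grades). Pre-operative segmentation models do not transfer to this
post-surgical morphology, and the scoring step is tedious to do by hand.

`gliotrack` implements the whole loop as an importable Python library:

* **`phantoms`** — synthetic post-operative phantom generator: dark cavity,
  enhancing rim/nodule on CE-T1w, FLAIR hyperintensity and blood product,
  nested ground-truth GTV1/GTV2 masks with closed-form volumes, and
  longitudinal series with prescribed volume trajectories.
* **`preprocess`** — resampling to a common grid (default 256×256×160),
  zero-mean/unit-variance normalization over nonzero voxels, brain-mask
  application, and the target-specific 3-channel input assembly
  (GTV1: stripped FLAIR / stripped CE-T1w / with-skull FLAIR;
  GTV2: stripped CE-T1w / stripped FLAIR / with-skull CE-T1w).
* **`model`** — a depth-3 3D U-Net with Dice loss
  `1 − (2Σpt+s)/(Σp+Σt+s)`, flip/90°-rotation augmentation (p = 0.5),
  plateau LR scheduling, 10-epoch early stopping, and sliding-window
  inference — implemented in pure NumPy with hand-derived backprop, so it
  runs anywhere SciPy does.
* **`metrics`** — Dice `2|A∩B|/(|A|+|B|)`, Jaccard `|A∩B|/|A∪B|`
  (J = D/(2−D)), and the *directed* Hausdorff distance (max over
  ground-truth voxels of the distance to the nearest predicted voxel, mm).
* **`cavity`** — 4-class multi-Otsu thresholding of CE-T1w intensities
  inside GTV2 and removal of the lowest class (the cavity), plus
  volumetry in cc.
* **`btrads`** — the volumetric decision tree: FLAIR changed ≥ 100% or
  enhancing grew ≥ 40% → 4; enhancing ≥ 20% or FLAIR ≥ 50% → 3
  (a shortly post-RT, c for a second consecutive worsening, b otherwise);
  mixed findings → 3b; both improved → 1; stable → 2.
* **`io`** — NIfTI case bundles, visit tables, and tracking reports
  (scores.json, volumes.csv, annotated plot).

## Worked example

```python
import gliotrack as gt
from gliotrack.btrads import VisitRecord

visits = [VisitRecord(date_days=0, flair_cc=10.0, enh_cc=4.0, is_baseline=True)]
fl, en = 10.0, 4.0
for days, rt, d_fl, d_en in [(60, 30, +26, +25), (120, 90, +37, +27),
                             (180, 150, -30, +12), (240, 210, 0, +70)]:
    fl, en = fl * (1 + d_fl / 100), en * (1 + d_en / 100)
    visits.append(VisitRecord(date_days=days, flair_cc=fl, enh_cc=en, days_since_rt=rt))

for v, r in zip(visits, gt.classify_series(visits)):
    print(v.date_days, round(v.flair_cc, 2), round(v.enh_cc, 2), r.code.upper())
```

prints

```
0 10.0 4.0 0
60 12.6 5.0 3A
120 17.26 6.35 3C
180 12.08 7.11 3B
240 12.08 12.09 4
```

— the canonical post-treatment course: baseline (0), worsening attributed
to treatment effect shortly after radiotherapy (3A), a second consecutive
worsening flagged as probable recurrence (3C), mixed findings (3B), and
recurrence once enhancing volume grows 70%, past the 40% cutoff (4).

The `examples/` directory has one narrative script per capability:
phantom generation with analytic-volume checks, training a small GTV1
segmenter on phantoms and evaluating Dice/Jaccard/Hausdorff, Otsu cavity
removal, BT-RADS tracking with report files, and the end-to-end
phantom-series → volumetry → scoring loop.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's reference quantities from scratch by running the
package: the BT-RADS codes assigned to the canonical visit scenarios
(baseline, post-RT worsening, consecutive worsening, mixed findings, the
+70% visit, and the exact 100%/40%/20% cutoff boundaries) and the
empirical augmentation flip frequency over 10,000 seeded draws, writing
one JSON object keyed by scenario. Sub-letters are encoded as tenths
(3A → 3.1, 3B → 3.2, 3C → 3.3).

## Scope

Phantoms are geometric (spheres, Gaussian noise, partial-volume blur) and
establish that the machinery works, not clinical accuracy; registration,
skull-stripping and bias-field correction are assumed done upstream. See
`docs/methods.md` for models, parameter defaults, design decisions and
limitations.
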