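"""Score a longitudinal visit series with the volumetric BT-RADS engine.

Reproduces the canonical post-treatment course: baseline (0), worsening
shortly after radiotherapy (3a), consecutive worsening (3c), mixed findings
(3b), and recurrence at +70% enhancing growth (4). Writes scores.json,
volumes.csv and an annotated volume-vs-time plot.
"""

import gliotrack as gt
from gliotrack.btrads import VisitRecord
from gliotrack.io import write_tracking_report

visits = [VisitRecord(date_days=0, flair_cc=10.0, enh_cc=4.0, is_baseline=True)]
fl, en = 10.0, 4.0
for days, rt, d_fl, d_en in [
    (60, 30, +26, +25),    # shortly post-RT
    (120, 90, +37, +27),   # second consecutive worsening
    (180, 150, -30, +12),  # FLAIR down, enhancement up
    (240, 210, 0, +70),    # recurrence-level enhancing growth
]:
    fl, en = fl * (1 + d_fl / 100), en * (1 + d_en / 100)
    visits.append(VisitRecord(date_days=days, flair_cc=fl, enh_cc=en, days_since_rt=rt))

results = gt.classify_series(visits)
print(f"{'day':>5} {'FLAIR cc':>9} {'ENH cc':>7}  score  rationale")
for v, r in zip(visits, results):
    print(f"{v.date_days:>5} {v.flair_cc:>9.2f} {v.enh_cc:>7.2f}  {r.code.upper():>5}  {r.rationale[0]}")

paths = write_tracking_report(visits, results, "scratch/tracking_report")
print(f"\nreport written: {paths['scores']}, {paths['volumes']}, {paths['plot']}")
# The score sequence 0, 3A, 3C, 3B, 4 shows every branch of the decision
# tree: treatment effect, consecutive worsening, mixed findings, recurrence.
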