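"""Automated BT-RADS scoring from longitudinal lesion volumes.

BT-RADS (Brain Tumor Reporting and Data System) grades each follow-up MRI
of a treated brain-tumor patient from 0 (post-surgery baseline) to 4
(highly suspicious for recurrence), with sub-grades 3a/3b/3c for worsening
imaging. This module reproduces a volumetric decision tree driven purely by
percent change in two lesion volumes between consecutive visits:

* FLAIR volume — the full T2w/FLAIR lesion (GTV1 segmentation);
* enhancing volume — the CE-T1w lesion after resection-cavity removal.

The recurrence cutoffs (FLAIR changed by >= 100%, enhancing increased by
>= 40%) and worsening cutoffs (enhancing >= 20%, FLAIR >= 50%) follow the
volumetric criteria established for RANO response assessment. A visit that
worsens below the recurrence cutoff for the second consecutive time is
escalated to 3c; worsening shortly after radiotherapy is attributed to
treatment effect (3a); mixed findings map to the indeterminate 3b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ParameterError, ValidationError

__all__ = [
    "VisitRecord",
    "CutoffParams",
    "VolumeChange",
    "ScoreResult",
    "percent_change",
    "classify_visit",
    "classify_series",
]


@dataclass(frozen=True)
class VisitRecord:
    """One longitudinal time point.

    Parameters
    ----------
    date_days
        Days since surgery (any strictly increasing clock works).
    flair_cc
        T2w/FLAIR lesion volume in cc (full GTV1 segmentation).
    enh_cc
        Enhancing CE-T1w lesion volume in cc, after cavity removal.
    days_since_rt
        Days since completion of radiotherapy, if known.
    is_baseline
        True for the post-surgery baseline scan (scored 0).
    """

    date_days: int
    flair_cc: float
    enh_cc: float
    days_since_rt: int | None = None
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.flair_cc < 0 or self.enh_cc < 0:
            raise ValidationError(
                f"lesion volumes must be >= 0, got flair={self.flair_cc}, enh={self.enh_cc}"
            )


@dataclass(frozen=True)
class CutoffParams:
    """Percent-change cutoffs and scoring knobs.

    ``flair_change_mode`` controls the FLAIR recurrence rule: the criterion
    is worded as the lesion having *changed* by 100% or greater, which read
    literally also fires on a 100% shrinkage (``"absolute"``, the default);
    ``"increase_only"`` restricts it to growth.
    """

    recurrence_flair_pct: float = 100.0
    recurrence_enh_pct: float = 40.0
    worsened_enh_pct: float = 20.0
    worsened_flair_pct: float = 50.0
    post_rt_window_days: int = 90
    stability_band_pct: float = 10.0
    min_measurable_cc: float = 0.1
    flair_change_mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.worsened_enh_pct >= self.recurrence_enh_pct:
            raise ParameterError("worsened enh cutoff must be below the recurrence cutoff")
        if self.worsened_flair_pct >= self.recurrence_flair_pct:
            raise ParameterError("worsened FLAIR cutoff must be below the recurrence cutoff")
        if self.flair_change_mode not in ("absolute", "increase_only"):
            raise ParameterError("flair_change_mode must be 'absolute' or 'increase_only'")


@dataclass(frozen=True)
class VolumeChange:
    """Percent change of one volume between consecutive visits.

    ``pct`` is None exactly when the lesion is newly measurable (division
    by an unmeasurable previous volume); ``resolved`` marks a measurable
    lesion falling below the measurability floor.
    """

    pct: float | None
    new_lesion: bool = False
    resolved: bool = False

    def increased_at_least(self, cutoff_pct: float) -> bool:
        """New lesions count as unbounded growth (inclusive comparison)."""
        return self.new_lesion or (self.pct is not None and self.pct >= cutoff_pct)

    def changed_at_least(self, cutoff_pct: float) -> bool:
        return self.new_lesion or (self.pct is not None and abs(self.pct) >= cutoff_pct)

    def decreased_beyond(self, band_pct: float) -> bool:
        return self.resolved or (self.pct is not None and self.pct <= -band_pct)


def percent_change(prev_cc: float, curr_cc: float, min_measurable_cc: float = 0.1) -> VolumeChange:
    """Percent volume change between two visits, with measurability guards.

    Returns ``(curr-prev)/prev*100`` when the previous volume is measurable;
    flags a new lesion when only the current volume is measurable; flags
    resolution when only the previous one was. Two unmeasurable volumes are
    reported as 0% change.
    """
    if prev_cc < 0 or curr_cc < 0:
        raise ValidationError("volumes must be non-negative")
    prev_meas = prev_cc >= min_measurable_cc
    curr_meas = curr_cc >= min_measurable_cc
    if not prev_meas and not curr_meas:
        return VolumeChange(pct=0.0)
    if not prev_meas:
        return VolumeChange(pct=None, new_lesion=True)
    pct = (curr_cc - prev_cc) / prev_cc * 100.0
    return VolumeChange(pct=pct, resolved=not curr_meas)


@dataclass
class ScoreResult:
    """A BT-RADS assignment with its rule trace."""

    major: int
    sub: str | None = None
    worsened_flag: bool = False
    rationale: list[str] = field(default_factory=list)
    flair_change: VolumeChange | None = None
    enh_change: VolumeChange | None = None

    @property
    def code(self) -> str:
        return f"{self.major}{self.sub or ''}"


def _classify_one(
    prev: VisitRecord | None,
    curr: VisitRecord,
    prev_worsened: bool,
    params: CutoffParams,
) -> ScoreResult:
    """Apply the decision tree to one visit given its predecessor state."""
    if curr.is_baseline:
        return ScoreResult(major=0, rationale=["baseline"])
    if prev is None:
        raise ValidationError("a non-baseline visit needs a preceding visit to compare against")

    d_fl = percent_change(prev.flair_cc, curr.flair_cc, params.min_measurable_cc)
    d_en = percent_change(prev.enh_cc, curr.enh_cc, params.min_measurable_cc)
    res = ScoreResult(major=2, flair_change=d_fl, enh_change=d_en)
    band = params.stability_band_pct

    # (2) tumor recurrence
    if params.flair_change_mode == "absolute":
        flair_recurred = d_fl.changed_at_least(params.recurrence_flair_pct)
    else:
        flair_recurred = d_fl.increased_at_least(params.recurrence_flair_pct)
    if flair_recurred or d_en.increased_at_least(params.recurrence_enh_pct):
        res.major, res.sub = 4, None
        if flair_recurred:
            res.rationale.append(f"recurrence: FLAIR changed >= {params.recurrence_flair_pct}%")
        if d_en.increased_at_least(params.recurrence_enh_pct):
            res.rationale.append(f"recurrence: enhancing grew >= {params.recurrence_enh_pct}%")
        return res

    # (3) worsened imaging below the recurrence cutoff
    if d_en.increased_at_least(params.worsened_enh_pct) or d_fl.increased_at_least(
        params.worsened_flair_pct
    ):
        res.major, res.worsened_flag = 3, True
        res.rationale.append(
            f"worsened: enhancing >= {params.worsened_enh_pct}% or "
            f"FLAIR >= {params.worsened_flair_pct}%"
        )
        if prev_worsened:
            res.sub = "c"
            res.rationale.append("second consecutive worsened visit")
        elif curr.days_since_rt is not None and curr.days_since_rt <= params.post_rt_window_days:
            res.sub = "a"
            res.rationale.append(
                f"within {params.post_rt_window_days} days of RT completion: treatment effect"
            )
        else:
            if curr.days_since_rt is None:
                warnings.warn(
                    "days_since_rt missing; cannot attribute worsening to treatment "
                    "effect, falling through to 3b",
                    stacklevel=3,
                )
            res.sub = "b"
            res.rationale.append("worsening not attributable to recent RT")
        return res

    # (4) mixed findings: one volume clearly down, the other clearly up
    fl_up, en_up = d_fl.increased_at_least(band), d_en.increased_at_least(band)
    fl_down, en_down = d_fl.decreased_beyond(band), d_en.decreased_beyond(band)
    if (fl_down and en_up) or (en_down and fl_up):
        res.major, res.sub = 3, "b"
        res.rationale.append("mixed findings: one volume decreased while the other increased")
        return res

    # (5) improved on both measures
    if fl_down and en_down:
        res.major = 1
        res.rationale.append("both volumes decreased beyond the stability band")
        return res

    # (6) stable
    res.major = 2
    res.rationale.append("volume changes within the stability band")
    return res


def classify_visit(
    history: list[VisitRecord], params: CutoffParams | None = None
) -> ScoreResult:
    """Score the last visit of ``history`` (all prior visits give context).

    The 3c escalation depends on whether the *previous* visit was itself
    worsened, so the predecessor's state is reconstructed by classifying the
    history prefix; :func:`classify_series` does the same incrementally.
    """
    if not history:
        raise ValidationError("history must contain at least one visit")
    params = params or CutoffParams()
    prev_worsened = False
    prev = None
    if len(history) > 1:
        prev = history[-2]
        prev_worsened = classify_visit(history[:-1], params).worsened_flag
    return _classify_one(prev, history[-1], prev_worsened, params)


def classify_series(
    visits: list[VisitRecord], params: CutoffParams | None = None
) -> list[ScoreResult]:
    """Score every visit of a longitudinal series in order.

    The series must be date-sorted with the baseline first; the worsened
    state is carried forward so consecutive sub-recurrence worsening
    escalates to 3c.
    """
    if not visits:
        raise ValidationError("series must contain at least one visit")
    dates = [v.date_days for v in visits]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValidationError(f"visit dates must be strictly increasing, got {dates}")
    if sum(v.is_baseline for v in visits) > 1:
        raise ValidationError("at most one baseline visit per series")
    if not visits[0].is_baseline:
        raise ValidationError("the first visit of a series must be the baseline")
    params = params or CutoffParams()
    results: list[ScoreResult] = []
    prev_worsened = False
    for prev, curr in zip([None, *visits[:-1]], visits):
        res = _classify_one(prev, curr, prev_worsened, params)
        prev_worsened = res.worsened_flag
        results.append(res)
    return results
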