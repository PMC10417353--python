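"""BT-RADS decision tree: worked example, boundaries, oracle equivalence."""

import numpy as np
import pytest

import gliotrack as gt
from gliotrack.btrads import CutoffParams, VisitRecord, VolumeChange
from gliotrack.errors import ParameterError, ValidationError


def visit(days, flair, enh, rt=None, baseline=False):
    return VisitRecord(
        date_days=days, flair_cc=flair, enh_cc=enh, days_since_rt=rt, is_baseline=baseline
    )


def series_for_changes(d_fl, d_en, rt=None, prev_worsened=False):
    """Build a series whose last visit has the given percent changes.

    With ``prev_worsened`` an intermediate worsened visit (enh +25%,
    FLAIR +26%, inside the post-RT window) is inserted, and the final
    changes are applied relative to it.
    """
    base_fl, base_en = 100.0, 50.0
    visits = [visit(0, base_fl, base_en, baseline=True)]
    if prev_worsened:
        base_fl, base_en = base_fl * 1.26, base_en * 1.25
        visits.append(visit(40, base_fl, base_en, rt=30))
    visits.append(
        visit(
            visits[-1].date_days + 60,
            base_fl * (1 + d_fl / 100),
            base_en * (1 + d_en / 100),
            rt=rt,
        )
    )
    return visits


def oracle_score(d_fl, d_en, prev_worsened=False, rt=None, p=CutoffParams()):
    """Independent flat re-coding of the published rule text (non-baseline,
    measurable volumes only)."""
    if abs(d_fl) >= p.recurrence_flair_pct or d_en >= p.recurrence_enh_pct:
        return (4, None)
    if d_en >= p.worsened_enh_pct or d_fl >= p.worsened_flair_pct:
        if prev_worsened:
            return (3, "c")
        if rt is not None and rt <= p.post_rt_window_days:
            return (3, "a")
        return (3, "b")
    b = p.stability_band_pct
    fl_up, en_up = d_fl >= b, d_en >= b
    fl_dn, en_dn = d_fl <= -b, d_en <= -b
    if (fl_dn and en_up) or (en_dn and fl_up):
        return (3, "b")
    if fl_dn and en_dn:
        return (1, None)
    return (2, None)


class TestPercentChange:
    def test_seventy_percent_growth(self):
        assert gt.percent_change(10.0, 17.0).pct == pytest.approx(70.0)

    def test_no_change(self):
        assert gt.percent_change(5.0, 5.0).pct == 0.0

    def test_new_lesion_flag(self):
        chg = gt.percent_change(0.0, 0.5)
        assert chg.new_lesion and chg.pct is None

    def test_resolution_flag(self):
        chg = gt.percent_change(2.0, 0.05)
        assert chg.resolved and chg.pct == pytest.approx(-97.5)

    def test_both_unmeasurable_is_zero(self):
        chg = gt.percent_change(0.01, 0.05)
        assert chg.pct == 0.0 and not chg.new_lesion

    def test_negative_volume_rejected(self):
        with pytest.raises(ValidationError):
            gt.percent_change(-1.0, 2.0)


class TestClassifyVisit:
    def test_baseline_scores_zero(self):
        res = gt.classify_visit([visit(0, 10, 4, baseline=True)])
        assert (res.major, res.sub) == (0, None)

    def test_worsened_shortly_after_rt_is_3a(self):
        """enh +25%, FLAIR +26% at 30 days post-RT: treatment effect (3a)."""
        res = gt.classify_visit(series_for_changes(26, 25, rt=30))
        assert (res.major, res.sub) == (3, "a")
        assert res.worsened_flag

    def test_second_consecutive_worsening_is_3c(self):
        res = gt.classify_visit(series_for_changes(37, 27, prev_worsened=True))
        assert (res.major, res.sub) == (3, "c")

    def test_mixed_findings_is_3b(self):
        res = gt.classify_visit(series_for_changes(-30, 12))
        assert (res.major, res.sub) == (3, "b")
        assert not res.worsened_flag

    def test_seventy_percent_enh_growth_is_4(self):
        res = gt.classify_visit(series_for_changes(0, 70))
        assert res.major == 4

    def test_exact_40_percent_enh_cutoff_inclusive(self):
        res = gt.classify_visit(series_for_changes(0, 40))
        assert res.major == 4

    def test_stable_inside_band_is_2(self):
        res = gt.classify_visit(series_for_changes(-5, 5))
        assert (res.major, res.sub) == (2, None)

    def test_both_improved_is_1(self):
        res = gt.classify_visit(series_for_changes(-40, -35))
        assert res.major == 1

    def test_new_enhancing_lesion_is_4(self):
        visits = [visit(0, 10, 0.0, baseline=True), visit(50, 10, 1.0)]
        assert gt.classify_visit(visits).major == 4

    def test_missing_days_since_rt_warns_and_gives_3b(self):
        with pytest.warns(UserWarning):
            res = gt.classify_visit(series_for_changes(0, 25, rt=None))
        assert (res.major, res.sub) == (3, "b")

    def test_empty_history_rejected(self):
        with pytest.raises(ValidationError):
            gt.classify_visit([])

    @pytest.mark.parametrize(
        "d_fl, d_en, expect_major",
        [
            (99.0, 0, 3), (100, 0, 4), (100 + 1e-6, 0, 4),
            (0, 40 - 1e-6, 3), (0, 40, 4), (0, 40 + 1e-6, 4),
            (0, 20 - 1e-6, 2), (0, 20, 3),
            (50 - 1e-6, 0, 2), (50, 0, 3),
        ],
    )
    def test_cutoff_boundaries_inclusive(self, d_fl, d_en, expect_major):
        res = gt.classify_visit(series_for_changes(d_fl, d_en, rt=200))
        assert res.major == expect_major


class TestClassifySeries:
    def test_five_visit_worked_example(self):
        """Baseline; +26/+25 post-RT; +37/+27; FLAIR down & enh up; enh +70.

        The canonical longitudinal course: 0, 3A, 3C, 3B, 4.
        """
        visits = [visit(0, 10.0, 4.0, baseline=True)]
        fl, en = 10.0, 4.0
        for days, rt, dfl, den in [
            (60, 30, 26, 25),
            (120, 90, 37, 27),
            (180, 150, -30, 12),
            (240, 210, 5, 70),
        ]:
            fl, en = fl * (1 + dfl / 100), en * (1 + den / 100)
            visits.append(visit(days, fl, en, rt=rt))
        codes = [r.code for r in gt.classify_series(visits)]
        assert codes == ["0", "3a", "3c", "3b", "4"]

    def test_all_stable_series(self):
        visits = [visit(0, 10, 4, baseline=True)] + [
            visit(30 * i, 10.0, 4.0, rt=200) for i in range(1, 4)
        ]
        majors = [r.major for r in gt.classify_series(visits)]
        assert majors == [0, 2, 2, 2]

    def test_matches_classify_visit_sequentially(self):
        visits = series_for_changes(37, 27, prev_worsened=True)
        series_results = gt.classify_series(visits)
        for k in range(1, len(visits) + 1):
            one = gt.classify_visit(visits[:k])
            assert (one.major, one.sub) == (series_results[k - 1].major, series_results[k - 1].sub)

    def test_unsorted_dates_rejected(self):
        visits = [visit(0, 10, 4, baseline=True), visit(0, 11, 4)]
        with pytest.raises(ValidationError):
            gt.classify_series(visits)

    def test_first_visit_must_be_baseline(self):
        with pytest.raises(ValidationError):
            gt.classify_series([visit(0, 10, 4), visit(30, 11, 4)])


GRID = [-100.0, -60.0, -30.0, -10.0, -9.9, -5.0, 0.0, 5.0, 9.9, 10.0, 19.9,
        20.0, 26.0, 39.9, 40.0, 49.9, 50.0, 70.0, 99.9, 100.0, 150.0]


class TestRuleTableOracle:
    @pytest.mark.parametrize("prev_worsened", [False, True])
    @pytest.mark.parametrize("rt", [30, 200, None])
    def test_exhaustive_boundary_grid(self, prev_worsened, rt):
        """Decision tree output equals the flat truth-table oracle on a grid
        straddling every cutoff."""
        import warnings

        for d_fl in GRID:
            for d_en in GRID:
                visits = series_for_changes(d_fl, d_en, rt=rt, prev_worsened=prev_worsened)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = gt.classify_visit(visits)
                # score the *effective* changes implied by the constructed
                # volumes, so float representation at exact cutoffs cannot
                # make oracle and classifier see different inputs
                prev, curr = visits[-2], visits[-1]
                eff_fl = (curr.flair_cc - prev.flair_cc) / prev.flair_cc * 100
                eff_en = (curr.enh_cc - prev.enh_cc) / prev.enh_cc * 100
                exp_major, exp_sub = oracle_score(eff_fl, eff_en, prev_worsened, rt)
                assert (res.major, res.sub) == (exp_major, exp_sub), (
                    f"d_fl={d_fl} d_en={d_en} rt={rt} prev_worsened={prev_worsened}: "
                    f"got {res.code}, expected {exp_major}{exp_sub or ''}"
                )


class TestProperties:
    @pytest.mark.parametrize("held_fl", [-30.0, -10.0, 0.0, 5.0, 50.0, 70.0])
    def test_major_monotone_in_enh_change(self, held_fl):
        """Increasing enhancing growth never lowers the major score.

        Holding FLAIR in the regions where the tree is monotone (the
        mixed-findings 3b rule intentionally breaks global monotonicity when
        the held measure sits between the stability band and the worsened
        cutoff).
        """
        majors = [
            gt.classify_visit(series_for_changes(held_fl, d_en, rt=200)).major
            for d_en in GRID
        ]
        assert majors == sorted(majors)

    @pytest.mark.parametrize("held_en", [-30.0, -10.0, 0.0, 5.0])
    def test_major_monotone_in_flair_change(self, held_en):
        """Same sweep over FLAIR growth (increase-only recurrence mode, so
        the literal |Δ|>=100% shrinkage rule does not fire at the low end)."""
        params = CutoffParams(flair_change_mode="increase_only")
        majors = [
            gt.classify_visit(series_for_changes(d_fl, held_en, rt=200), params).major
            for d_fl in GRID
        ]
        assert majors == sorted(majors)

    def test_flair_full_resolution_fires_recurrence_in_absolute_mode(self):
        """The literal reading: FLAIR 'changed by 100%' includes shrinkage."""
        res = gt.classify_visit(series_for_changes(-100.0, 0.0))
        assert res.major == 4
        res2 = gt.classify_visit(
            series_for_changes(-100.0, 0.0), CutoffParams(flair_change_mode="increase_only")
        )
        assert res2.major != 4

    def test_3c_never_first_worsened_visit(self):
        for d_fl in GRID:
            for d_en in GRID:
                visits = series_for_changes(d_fl, d_en, rt=200)
                res = gt.classify_visit(visits)
                if res.major == 3:
                    assert res.sub != "c"

    def test_cutoff_params_ordering_enforced(self):
        with pytest.raises(ParameterError):
            CutoffParams(worsened_enh_pct=50.0)  # above the 40% recurrence cutoff

    def test_volume_change_helpers(self):
        chg = VolumeChange(pct=-12.0)
        assert chg.decreased_beyond(10) and not chg.increased_at_least(10)
        assert VolumeChange(pct=None, new_lesion=True).increased_at_least(1000)
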