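"""Evaluation metrics, AAMI verdicts, BHS grading, Bland-Altman."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mwppg import (
    EvalReport,
    aami_check,
    bhs_grade,
    bland_altman,
    compute_metrics,
    grade_from_percentages,
    limits_of_agreement,
    render_report,
    rmse_from_me_sd,
)
from mwppg.errors import SampleSizeError, ShapeError

finite_errors = st.lists(
    st.floats(min_value=-60, max_value=60, allow_nan=False), min_size=2, max_size=50
)


class TestComputeMetrics:
    def test_perfect_prediction(self):
        y = np.array([120.0, 130.0, 110.0])
        r = compute_metrics(y, y)
        assert (r.me, r.sd, r.mae, r.rmse) == (0, 0, 0, 0)
        assert r.r2 == 1.0

    def test_constant_offset(self):
        y = np.array([120.0, 130.0, 110.0])
        r = compute_metrics(y, y + 2.0)
        assert r.me == pytest.approx(2.0)
        assert r.mae == pytest.approx(2.0)
        assert r.sd == pytest.approx(0.0)
        assert r.rmse == pytest.approx(2.0)

    def test_symmetric_errors_direct_arithmetic(self):
        # errors (+1, -1, +3, -3): ME=0, MAE=2, RMSE=SD=sqrt(5)
        y = np.zeros(4)
        pred = np.array([1.0, -1.0, 3.0, -3.0])
        r = compute_metrics(y, pred)
        assert r.me == pytest.approx(0.0)
        assert r.mae == pytest.approx(2.0)
        assert r.rmse == pytest.approx(np.sqrt(5), abs=1e-12)
        assert r.sd == pytest.approx(np.sqrt(5), abs=1e-12)

    def test_r2_matches_sklearn(self, rng):
        from sklearn.metrics import r2_score

        y = rng.normal(120, 10, 50)
        p = y + rng.normal(0, 5, 50)
        assert compute_metrics(y, p).r2 == pytest.approx(r2_score(y, p), abs=1e-12)

    def test_too_few_samples_and_length_mismatch(self):
        with pytest.raises(SampleSizeError):
            compute_metrics([120.0], [118.0])
        with pytest.raises(ShapeError):
            compute_metrics([120.0, 121.0], [118.0])

    @given(finite_errors)
    @settings(deadline=None, max_examples=50)
    def test_rmse_identity_and_jensen(self, errs):
        errs = np.asarray(errs)
        y = np.full(errs.size, 120.0)
        r = compute_metrics(y, y + errs)
        # population-SD identity RMSE^2 = ME^2 + SD^2 (table consistency)
        assert r.rmse**2 == pytest.approx(r.me**2 + r.sd**2, abs=1e-6)
        assert r.mae <= r.rmse + 1e-12


class TestAAMI:
    @pytest.mark.parametrize(
        "me,sd,expected",
        [
            (0.90, 7.66, True),    # single best channel, SBP
            (0.58, 8.72, False),   # worst channel SD exceeds 8
            (5.0, 7.0, False),     # boundary is strict
            (-4.99, 7.99, True),
            (4.99, 8.0, False),
        ],
    )
    def test_verdicts(self, me, sd, expected):
        assert aami_check(me, sd) is expected

    def test_matches_compute_metrics_output(self, rng):
        y = rng.normal(120, 10, 200)
        p = y + rng.normal(1.0, 5.0, 200)
        r = compute_metrics(y, p)
        assert r.aami_pass == aami_check(r.me, r.sd)


class TestBHS:
    @pytest.mark.parametrize(
        "pcts,grade",
        [
            ((94, 96, 97), "A"),
            ((60, 85, 95), "A"),    # thresholds inclusive
            ((59, 95, 99), "B"),
            ((40, 65, 85), "C"),
            ((25, 50, 75), "D"),
        ],
    )
    def test_grade_from_percentages(self, pcts, grade):
        assert grade_from_percentages(*pcts) == grade

    def test_counting_from_absolute_errors(self):
        res = bhs_grade([1.0, 6.0, 12.0, 20.0])
        assert res.percentages == (25.0, 50.0, 75.0)
        assert res.grade == "D"

    def test_cumulative_percentages_non_decreasing(self, rng):
        res = bhs_grade(np.abs(rng.normal(0, 8, 500)))
        assert res.pct5 <= res.pct10 <= res.pct15

    @given(finite_errors)
    @settings(deadline=None, max_examples=50)
    def test_adding_zero_error_never_lowers_grade(self, errs):
        order = "DCBA"
        before = bhs_grade(np.abs(errs))
        after = bhs_grade(np.abs(errs + [0.0]))
        assert order.index(after.grade) >= order.index(before.grade)

    def test_empty_input_rejected(self):
        with pytest.raises(SampleSizeError):
            bhs_grade([])


class TestBlandAltman:
    def test_reported_dbp_interval_reproduced(self):
        lo, hi = limits_of_agreement(0.711, 2.43)
        assert lo == pytest.approx(-4.052, abs=5e-4)
        assert hi == pytest.approx(5.474, abs=5e-4)

    def test_reported_sbp_interval_within_rounding(self):
        lo, hi = limits_of_agreement(0.216, 5.28)
        assert lo == pytest.approx(-10.129, abs=0.01)
        assert hi == pytest.approx(10.560, abs=0.01)

    def test_zero_errors_give_degenerate_limits(self):
        y = np.array([100.0, 120.0, 140.0])
        ba = bland_altman(y, y)
        assert (ba.mean_diff, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)

    def test_consistent_with_compute_metrics(self, rng):
        y = rng.normal(120, 10, 100)
        p = y + rng.normal(0, 4, 100)
        r = compute_metrics(y, p)
        ba = bland_altman(y, p)
        assert ba.mean_diff == pytest.approx(r.me)
        assert ba.loa_low == pytest.approx(r.me - 1.96 * r.sd)

    def test_single_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            bland_altman([120.0], [118.0])


class TestRMSEIdentityAgainstTables:
    @pytest.mark.parametrize(
        "me,sd,rmse",
        [
            (0.71, 2.43, 2.53),   # fused-input DBP
            (-0.36, 5.65, 5.66),  # branch-input SBP
            (0.58, 8.72, 8.74),   # worst single channel SBP
            (-0.32, 4.07, 4.08),  # best single channel DBP
        ],
    )
    def test_reported_rmse_cells_reconstructed(self, me, sd, rmse):
        assert rmse_from_me_sd(me, sd) == pytest.approx(rmse, abs=5e-3)


class TestRenderReport:
    def test_json_round_trips_and_files_exist(self, tmp_path, rng):
        y = rng.normal(120, 10, 60)
        p = y + rng.normal(0, 4, 60)
        report = compute_metrics(y, p)
        paths = render_report(report, tmp_path, label="SBP")
        data = json.loads(paths["json"].read_text())
        back = EvalReport.from_dict(data)
        assert back.mae == pytest.approx(report.mae)
        assert back.bhs.grade == report.bhs.grade
        assert paths["plot"].stat().st_size > 0
        table = paths["table"].read_text()
        assert "Grade A: 60 85 95" in table
        assert "Grade C: 40 65 85" in table
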