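"""Sensitivity/specificity arithmetic, exact intervals, session summaries."""

import numpy as np
import pytest
from scipy import stats

from coughval.detector_eval import (
    BinomialCI,
    ContingencyTable,
    contingency,
    exact_binomial_ci,
    metric_summary,
    per_session_metrics,
    pooled_metrics,
    sensitivity,
    specificity,
)
from coughval.gold_standard import AnalysisSecond, DeviceSecond, GoldClass


def cp_bisection_oracle(successes, n, confidence=0.95, tol=1e-12):
    """Independent Clopper-Pearson oracle: bisection on the binomial tails."""
    alpha = 1 - confidence

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    if successes == 0:
        lower = 0.0
    else:
        # largest p with P(X >= s | p) <= alpha/2
        lower = bisect(
            lambda p: stats.binom.sf(successes - 1, n, p) <= alpha / 2, 0.0, 1.0
        )
    if successes == n:
        upper = 1.0
    else:
        # smallest p with P(X <= s | p) <= alpha/2  (scan from above)
        upper = 1.0 - bisect(
            lambda q: stats.binom.cdf(successes, n, 1 - q) <= alpha / 2, 0.0, 1.0
        )
    return lower, upper


def _cough_seconds(n, detected, session="s", device="phone1", start=0):
    return [
        AnalysisSecond(session, start + i, GoldClass.TRUE_COUGH,
                       {device: DeviceSecond(i < detected, 0.9 if i < detected else None)})
        for i in range(n)
    ]


def _noncough_seconds(n, detected, session="s", device="phone1", start=10_000):
    return [
        AnalysisSecond(session, start + i, GoldClass.NON_COUGH,
                       {device: DeviceSecond(i < detected, 0.9 if i < detected else None)})
        for i in range(n)
    ]


class TestAccuracyArithmetic:
    @pytest.mark.parametrize(
        "tp, fn, expected_pct",
        [(615, 57, 91.5), (622, 50, 92.56), (0, 10, 0.0)],
    )
    def test_sensitivity(self, tp, fn, expected_pct):
        assert 100 * sensitivity(ContingencyTable(tp, 0, fn, 0)) == pytest.approx(
            expected_pct, abs=0.05
        )

    @pytest.mark.parametrize(
        "fp, tn, expected_pct",
        [(7, 1000, 99.3), (13, 994, 98.71), (0, 100, 100.0)],
    )
    def test_specificity(self, fp, tn, expected_pct):
        assert 100 * specificity(ContingencyTable(0, fp, 0, tn)) == pytest.approx(
            expected_pct, abs=0.05
        )

    def test_undefined_metrics_raise(self):
        with pytest.raises(ValueError, match="sensitivity undefined"):
            sensitivity(ContingencyTable(0, 5, 0, 5))
        with pytest.raises(ValueError, match="specificity undefined"):
            specificity(ContingencyTable(5, 0, 5, 0))


class TestContingency:
    def test_reproduces_study_marginals(self):
        """672 cough-seconds (615 detected) and 1007 non-cough (7 detected)."""
        secs = _cough_seconds(672, 615) + _noncough_seconds(1007, 7)
        ct = contingency(secs, "phone1")
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (615, 7, 57, 1000)
        assert ct.n_cough_seconds == 672
        assert ct.n_noncough_seconds == 1007
        assert ct.tp + ct.fp + ct.fn + ct.tn == 1679

    def test_no_detections_gives_zero_positives(self):
        secs = _cough_seconds(5, 0) + _noncough_seconds(5, 0)
        ct = contingency(secs, "phone1")
        assert (ct.tp, ct.fp) == (0, 0)

    def test_perfect_detector_gives_zero_errors(self):
        secs = _cough_seconds(5, 5) + _noncough_seconds(5, 0)
        ct = contingency(secs, "phone1")
        assert (ct.fn, ct.fp) == (0, 0)

    def test_disagreement_seconds_excluded(self):
        secs = _cough_seconds(5, 5) + [
            AnalysisSecond("s", 999, GoldClass.DISPUTED,
                           {"phone1": DeviceSecond(True, 0.99)})
        ]
        ct = contingency(secs, "phone1")
        assert ct.tp + ct.fp + ct.fn + ct.tn == 5

    def test_pooled_equals_sum_of_sessions(self):
        by_session = {
            "s1": _cough_seconds(20, 18, "s1") + _noncough_seconds(30, 1, "s1"),
            "s2": _cough_seconds(15, 10, "s2") + _noncough_seconds(25, 0, "s2"),
        }
        pooled = pooled_metrics(by_session, "phone1")
        total = ContingencyTable(0, 0, 0, 0)
        for secs in by_session.values():
            total = total + contingency(secs, "phone1")
        assert pooled["table"] == total


class TestExactInterval:
    def test_boundary_counts(self):
        assert exact_binomial_ci(0, 20).lower == 0.0
        assert exact_binomial_ci(20, 20).upper == 1.0

    def test_against_bisection_oracle_8_of_10(self):
        ci = exact_binomial_ci(8, 10)
        lo, hi = cp_bisection_oracle(8, 10)
        assert ci.lower == pytest.approx(lo, abs=1e-6)
        assert ci.upper == pytest.approx(hi, abs=1e-6)

    def test_study_counts(self):
        ci = exact_binomial_ci(615, 672)
        lo, hi = cp_bisection_oracle(615, 672)
        assert ci.lower == pytest.approx(lo, abs=1e-6)
        assert ci.upper == pytest.approx(hi, abs=1e-6)

    def test_invalid_counts_raise(self):
        for bad in [(-1, 10), (11, 10), (0, 0)]:
            with pytest.raises(ValueError):
                exact_binomial_ci(*bad)

    def test_ordering_invariant(self):
        ci = exact_binomial_ci(5, 12)
        assert 0 <= ci.lower <= ci.estimate <= ci.upper <= 1

    def test_interval_ordering_enforced(self):
        with pytest.raises(ValueError):
            BinomialCI(0.5, 0.6, 0.9)


class TestPerSession:
    def test_median_of_three_sessions(self):
        by_session = {
            "s1": _cough_seconds(10, 5, "s1") + _noncough_seconds(5, 0, "s1"),
            "s2": _cough_seconds(10, 9, "s2") + _noncough_seconds(5, 0, "s2"),
            "s3": _cough_seconds(10, 10, "s3") + _noncough_seconds(5, 0, "s3"),
        }
        frame, summaries = per_session_metrics(by_session)
        assert sorted(frame.sensitivity) == [0.5, 0.9, 1.0]
        assert summaries["phone1"]["sensitivity"].median == pytest.approx(0.9)

    def test_all_perfect_sessions(self):
        by_session = {
            f"s{i}": _cough_seconds(10, 10, f"s{i}") + _noncough_seconds(5, 0, f"s{i}")
            for i in range(3)
        }
        _, summaries = per_session_metrics(by_session)
        s = summaries["phone1"]["sensitivity"]
        assert (s.minimum, s.median, s.maximum) == (1.0, 1.0, 1.0)

    def test_session_without_gold_coughs_skipped_with_nan(self, caplog):
        by_session = {
            "s1": _cough_seconds(10, 9, "s1") + _noncough_seconds(5, 0, "s1"),
            "s2": _noncough_seconds(5, 0, "s2"),  # nothing to evaluate sensitivity on
        }
        with caplog.at_level("WARNING"):
            frame, summaries = per_session_metrics(by_session)
        assert frame.sensitivity.isna().sum() == 1
        assert "not evaluated" in caplog.text
        assert summaries["phone1"]["sensitivity"].median == pytest.approx(0.9)

    def test_order_invariance(self):
        a = {"s1": _cough_seconds(10, 5, "s1"), "s2": _cough_seconds(10, 9, "s2")}
        b = dict(reversed(list(a.items())))
        fa, _ = per_session_metrics(a)
        fb, _ = per_session_metrics(b)
        assert fa.sensitivity.tolist() == fb.sensitivity.tolist()


def test_metric_summary_is_linear_interpolated_quantiles():
    vals = [0.2, 0.4, 0.6, 1.0]
    s = metric_summary(vals)
    assert (s.minimum, s.maximum) == (0.2, 1.0)
    assert s.q1 == pytest.approx(np.quantile(vals, 0.25))
    assert s.minimum <= s.q1 <= s.median <= s.q3 <= s.maximum
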