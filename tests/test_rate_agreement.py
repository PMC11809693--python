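"""Per-minute segmentation, correlation/fit and Bland-Altman agreement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coughval import pipeline as pl
from coughval import rate_agreement as ra
from coughval import synthetic_data as sd
from coughval.gold_standard import GoldClass


def test_ten_minute_session_has_ten_segments():
    series = ra.segment_counts({5}, {"phone1": set()}, duration=600.0)
    assert series.frame.segment_index.nunique() == 10


def test_counts_fall_in_their_minutes():
    series = ra.segment_counts({5, 65, 66}, {"phone1": {5}}, duration=600.0)
    gold = series.frame.sort_values("segment_index").gold_count.tolist()
    assert gold == [1, 2, 0, 0, 0, 0, 0, 0, 0, 0]
    assert series.frame.device_count.sum() == 1


@pytest.mark.parametrize("duration, n_expected", [(630.0, 11), (620.0, 10), (90.0, 2), (80.0, 1)])
def test_final_partial_segment_kept_iff_at_least_half(duration, n_expected):
    series = ra.segment_counts(set(), {"phone1": set()}, duration=duration)
    assert series.frame.segment_index.nunique() == n_expected


def test_counts_match_brute_force_tally(small_cohort):
    """Segment counts equal a direct per-minute tally of the same seconds."""
    results = pl.evaluate_cohort(small_cohort)
    r = results[0]
    series = ra.segment_counts(
        r.gold_cough_seconds, r.device_cough_seconds, r.manifest.duration
    )
    for seg, sub in series.frame.groupby("segment_index"):
        lo, hi = 60 * seg, 60 * (seg + 1)
        assert sub.gold_count.iloc[0] == sum(
            1 for s in r.gold_cough_seconds if lo <= s < hi
        )
        assert sub.device_count.iloc[0] == sum(
            1 for s in r.device_cough_seconds["phone1"] if lo <= s < hi
        )


def test_segment_gold_sum_conserved(small_cohort):
    results = pl.evaluate_cohort(small_cohort)
    series = ra.concat_series(
        [
            ra.segment_counts(r.gold_cough_seconds, r.device_cough_seconds,
                              r.manifest.duration, session_id=r.manifest.session_id)
            for r in results
        ]
    )
    total_gold = sum(len(r.gold_cough_seconds) for r in results)
    per_device = series.frame.groupby("device_id").gold_count.sum()
    assert (per_device == total_gold).all()


class TestCorrelate:
    def test_identity_series(self):
        gold = [0, 1, 2, 3, 5, 2]
        res = ra.correlate(gold, gold)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_doubled_counts(self):
        gold = [0, 1, 2, 3]
        res = ra.correlate(gold, [2 * g for g in gold])
        assert res.slope == pytest.approx(2.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            ra.correlate([2, 2, 2, 2], [1, 2, 3, 4])

    def test_too_few_segments_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            ra.correlate([1, 2], [1, 2])

    @given(st.permutations(list(range(8))))
    def test_permutation_invariance(self, order):
        gold = np.array([0, 1, 2, 3, 4, 0, 2, 5])
        dev = np.array([0, 1, 1, 3, 5, 1, 2, 4])
        base = ra.correlate(gold, dev)
        perm = ra.correlate(gold[order], dev[order])
        assert perm.pearson_r == pytest.approx(base.pearson_r)
        assert perm.slope == pytest.approx(base.slope)


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_limits(self):
        ba = ra.bland_altman_pct([1, 2, 3], [1, 2, 3])
        assert ba.mean_pct_error == 0.0
        assert (ba.loa_lower, ba.loa_upper) == (0.0, 0.0)

    def test_symmetric_errors(self):
        ba = ra.bland_altman_pct([10, 10], [11, 9])
        assert ba.mean_pct_error == pytest.approx(0.0)
        assert ba.loa_upper == pytest.approx(-ba.loa_lower)

    def test_zero_gold_segments_excluded(self):
        ba = ra.bland_altman_pct([0, 2, 4], [3, 2, 4])
        assert ba.n_segments_used == 2
        assert ba.mean_pct_error == pytest.approx(0.0)

    def test_no_usable_segments_raises(self):
        with pytest.raises(ValueError, match="no segments"):
            ra.bland_altman_pct([0, 0], [1, 2])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        gold = rng.integers(1, 8, 40)
        dev = np.maximum(gold + rng.integers(-2, 3, 40), 0)
        ba = ra.bland_altman_pct(gold, dev)
        pct = 100 * (dev - gold) / gold
        assert ba.mean_pct_error == pytest.approx(pct.mean())
        assert ba.loa_upper == pytest.approx(pct.mean() + 1.96 * pct.std(ddof=1))


def test_simulated_slope_tracks_detector_sensitivity():
    """With a 92%-sensitive detector and perfect annotators the pooled fit
    slope approaches the injected sensitivity (wide tolerance, many seeds)."""
    slopes, rs = [], []
    for seed in range(20):
        params = sd.SimulatorParams(
            seed=500 + seed, n_sessions=4, devices=("phone1",),
            annotators=(sd.PERFECT_ANNOTATOR,) * 3,
        )
        results = pl.evaluate_cohort(sd.simulate_cohort(params))
        included = [r for r in results if r.qc.included]
        series = ra.concat_series(
            [
                ra.segment_counts(r.gold_cough_seconds, r.device_cough_seconds,
                                  r.manifest.duration, session_id=r.manifest.session_id)
                for r in included
            ]
        )
        res = ra.evaluate_agreement(series)["pooled"]
        slopes.append(res.slope)
        rs.append(res.pearson_r)
    assert np.mean(slopes) == pytest.approx(0.92, abs=0.15)
    assert np.mean(rs) > 0.9


def test_plot_files_written(tmp_path, small_cohort):
    results = pl.evaluate_cohort(small_cohort)
    r = results[0]
    series = ra.segment_counts(
        r.gold_cough_seconds, r.device_cough_seconds, r.manifest.duration
    )
    ra.plot_rate_scatter(series, tmp_path / "scatter.png")
    ra.plot_bland_altman(series, tmp_path / "ba.png")
    assert (tmp_path / "scatter.png").stat().st_size > 0
    assert (tmp_path / "ba.png").stat().st_size > 0


def test_agreement_result_keys(small_cohort):
    results = pl.evaluate_cohort(small_cohort)
    series = ra.concat_series(
        [
            ra.segment_counts(r.gold_cough_seconds, r.device_cough_seconds,
                              r.manifest.duration, session_id=r.manifest.session_id)
            for r in results
        ]
    )
    out = ra.evaluate_agreement(series)
    assert set(out) == {"phone1", "pooled"}
    for res in out.values():
        ba = res.bland_altman
        assert ba.loa_lower <= ba.mean_pct_error <= ba.loa_upper
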