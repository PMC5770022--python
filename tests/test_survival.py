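"""Interval construction, log-normal MLE and percentile-table contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laborkinetics.cohort import LabourRecord
from laborkinetics.survival import (
    IntervalDatum,
    LogNormalFit,
    admission_to_level_data,
    cumulative_duration_table,
    fit_lognormal,
    fit_lognormal_brackets,
    lognormal_percentiles,
    reaching_intervals,
    sojourn_data,
    sojourn_pair_data,
    sojourn_table,
    staircase_series,
)


def _record(exams, full, **kw):
    return LabourRecord(woman_id=kw.pop("woman_id", "w"), parity_group="0",
                        exams=exams, full_dilatation_time_h=full, **kw)


class TestReachingIntervals:
    def test_direct_bracketing(self):
        rec = _record([(0.0, 4), (3.0, 6)], full=6.0)
        reach = reaching_intervals(rec)
        assert reach[4].exact and reach[4].lower == 0.0  # admission level
        assert (reach[5].lower, reach[5].upper, reach[5].exact) == (0.0, 3.0, False)
        assert (reach[6].lower, reach[6].upper, reach[6].exact) == (0.0, 3.0, False)
        assert reach[10].exact and reach[10].lower == 6.0
        assert 3 not in reach  # below admission: reached before observation

    def test_exam_at_each_change_gives_exact_intervals(self):
        rec = _record([(0.0, 4), (1.0, 5), (2.5, 6), (3.0, 7), (3.5, 8)],
                      full=4.0)
        reach = reaching_intervals(rec)
        # zero-width brackets collapse to exact reaching times
        assert reach[5].exact is False  # (0, 1]: still a bracket, not exact
        assert reach[10].exact

    def test_regressing_dilatations_rejected(self):
        rec = _record([(0.0, 5), (1.0, 4), (2.0, 10)], full=2.0)
        with pytest.raises(ValueError, match="regress"):
            reaching_intervals(rec)

    def test_true_reaching_times_inside_intervals(self, parity0_cohort):
        for rec in parity0_cohort[:300]:
            path = rec.meta["path"]
            reach = reaching_intervals(rec)
            for d, iv in reach.items():
                true_t = path.reaching_time[d] - path.admission_time
                assert iv.lower - 1e-9 <= true_t <= iv.upper + 1e-9


class TestSojournData:
    def test_bounds_arithmetic(self):
        # reaching(4) in (0, 2], reaching(5) in (2, 5] -> sojourn in [0, 5]
        rec = _record([(0.0, 3), (2.0, 4), (5.0, 5), (6.0, 8)], full=7.0)
        data = sojourn_data([rec], (4, 5))
        assert len(data) == 1
        assert (data[0].lower, data[0].upper) == (0.0, 5.0)

    def test_exact_pair_gives_exact_datum(self):
        rec = _record([(0.0, 8)], full=2.0)
        data = sojourn_data([rec], (8, 10))
        assert data[0].exact and data[0].lower == pytest.approx(2.0)

    def test_admission_above_origin_excluded(self):
        rec = _record([(0.0, 5), (2.0, 10)], full=2.0)
        assert sojourn_data([rec], (4, 5)) == []

    def test_true_sojourns_inside_bounds(self, parity0_cohort):
        for tr in [(3, 4), (5, 6), (8, 10)]:
            data = sojourn_data(parity0_cohort[:400], tr)
            by_id = {r.woman_id: r for r in parity0_cohort[:400]}
            for datum in data:
                path = by_id[datum.woman_id].meta["path"]
                truth = path.reaching_time[tr[1]] - path.reaching_time[tr[0]]
                assert datum.lower - 1e-9 <= truth <= datum.upper + 1e-9


class TestFitLognormal:
    def test_exact_data_reduces_to_closed_form(self):
        rng = np.random.default_rng(5)
        t = rng.lognormal(0.3, 0.7, size=200)
        fit = fit_lognormal([IntervalDatum(x, x, True) for x in t])
        assert fit.converged
        assert fit.mu == pytest.approx(np.mean(np.log(t)), abs=1e-5)
        assert fit.sigma == pytest.approx(np.std(np.log(t)), abs=1e-4)

    def test_degenerate_equal_exact_data_rejected(self):
        data = [IntervalDatum(2.0, 2.0, True) for _ in range(20)]
        with pytest.raises(ValueError, match="degenerate"):
            fit_lognormal(data)

    def test_too_few_informative_rejected(self):
        with pytest.raises(ValueError, match="informative"):
            fit_lognormal([IntervalDatum(1.0, 1.0, True)] * 5)

    def test_left_and_right_censoring_handled(self):
        rng = np.random.default_rng(6)
        t = rng.lognormal(0.0, 0.8, size=3000)
        data = []
        for x in t:  # censor at fixed inspection 1.0 h
            if x < 1.0:
                data.append(IntervalDatum(0.0, 1.0, False))
            else:
                data.append(IntervalDatum(1.0, np.inf, False))
        fit = fit_lognormal(data)
        # a single binary split identifies only P(T < 1); check that
        from scipy.stats import norm
        p_below = norm.cdf((math.log(1.0) - fit.mu) / fit.sigma)
        assert p_below == pytest.approx(np.mean(t < 1.0), abs=0.02)

    def test_matches_lifelines_on_mixed_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(8)
        t = rng.lognormal(0.4, 0.9, size=1500)
        lo = np.floor(t / 0.8) * 0.8
        hi = lo + 0.8
        data = [IntervalDatum(a, b, False) for a, b in zip(lo, hi)]
        fit = fit_lognormal(data)
        lnf = lifelines.LogNormalFitter()
        lnf.fit_interval_censoring(np.maximum(lo, 1e-6), hi)
        assert fit.mu == pytest.approx(lnf.mu_, abs=2e-3)
        assert fit.sigma == pytest.approx(lnf.sigma_, abs=2e-3)

    def test_shrinking_interval_limit(self, parity0_truth):
        # hourly vs 6-minute exams for admission-at-4 women: the interval MLE
        # approaches the complete-data MLE as brackets shrink
        mu_t, sig_t = parity0_truth.sojourn_params[(4, 5)]
        rng = np.random.default_rng(9)
        t = rng.lognormal(mu_t, sig_t, size=1500)
        results = {}
        for gap in (2.0, 0.1):
            data = []
            for x in t:
                k = math.floor(x / gap)
                data.append(IntervalDatum(k * gap, (k + 1) * gap, False))
            results[gap] = fit_lognormal(data)
        mu_complete = float(np.mean(np.log(t)))
        assert abs(results[0.1].mu - mu_complete) < 0.02
        assert abs(results[0.1].mu - mu_complete) < abs(results[2.0].mu - mu_complete)


class TestPercentiles:
    def test_median_is_exp_mu(self):
        fit = LogNormalFit(mu=0.0, sigma=1.3, loglik=0, n_exact=1,
                           n_interval=0, converged=True)
        assert lognormal_percentiles(fit, (0.5,))[0] == pytest.approx(1.0)

    def test_calibrated_p95(self):
        fit = LogNormalFit(mu=math.log(1.72), sigma=0.9213, loglik=0,
                           n_exact=1, n_interval=0, converged=True)
        assert lognormal_percentiles(fit, (0.95,))[0] == pytest.approx(7.83, abs=5e-3)

    def test_invalid_probability(self):
        fit = LogNormalFit(0, 1, 0, 1, 0, True)
        with pytest.raises(ValueError):
            lognormal_percentiles(fit, (1.5,))

    @given(mu=st.floats(-2, 2), sigma=st.floats(0.05, 2.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_quantile_ordering(self, mu, sigma):
        fit = LogNormalFit(mu, sigma, 0, 1, 0, True)
        p5, p50, p95 = lognormal_percentiles(fit)
        assert p5 <= p50 <= p95


class TestTables:
    def test_sojourn_table_recovers_slow_transitions(self, parity0_cohort,
                                                     parity0_truth):
        table = sojourn_table(parity0_cohort, parity_label="0")
        assert (table.p5 <= table.p50).all() and (table.p50 <= table.p95).all()
        for tr in [(3, 4), (4, 5)]:
            row = table[(table.from_cm == tr[0]) & (table.to_cm == tr[1])]
            truth_median = math.exp(parity0_truth.sojourn_params[tr][0])
            assert row.p50.iloc[0] == pytest.approx(truth_median, rel=0.25)

    def test_cumulative_table_monotone(self, parity0_cohort):
        table = cumulative_duration_table(parity0_cohort, parity_label="0")
        assert (table.p5 <= table.p50).all() and (table.p50 <= table.p95).all()
        for adm, sub in table.groupby("admission_cm"):
            sub = sub.sort_values("to_cm")
            assert sub.p50.is_monotonic_increasing

    def test_single_transition_stratum_equals_sojourn_fit(self, parity0_cohort):
        adm6 = [r for r in parity0_cohort if r.admission_dilatation == 6]
        cum = admission_to_level_data(adm6, 6, 7)
        pairs = sojourn_pair_data(adm6, (6, 7))
        fit_cum = fit_lognormal(cum)
        fit_soj = fit_lognormal_brackets(pairs)
        assert fit_soj.mu == pytest.approx(fit_cum.mu, abs=1e-4)
        assert fit_soj.sigma == pytest.approx(fit_cum.sigma, abs=1e-4)

    def test_staircase_contracts(self, parity0_cohort):
        table = cumulative_duration_table(parity0_cohort, parity_label="0")
        steps95 = staircase_series(table, 4, prob=0.95)
        steps50 = staircase_series(table, 4, prob=0.5)
        hours95 = [h for _, h in steps95]
        assert hours95 == sorted(hours95)
        assert all(h50 <= h95 for (_, h50), (_, h95) in zip(steps50, steps95))
        with pytest.raises(ValueError):
            staircase_series(table, 2)
        with pytest.raises(ValueError):
            staircase_series(table, 4, prob=0.42)
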