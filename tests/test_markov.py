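"""Matrix-exponential likelihood, chain simulation and table contracts."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from laborkinetics.markov import (
    IntensityMatrix,
    N_TRANSIENT,
    PanelSeries,
    STATE_VALUES,
    _eig_P_entries,
    average_curve_markov,
    fit_intensities,
    markov_cumulative_table,
    markov_sojourn_table,
    panel_log_likelihood,
    records_to_panels,
    simulate_markov_cohort,
    state_index,
    transition_probability,
)

RATES = np.array([0.38, 0.40, 0.44, 0.84, 0.75, 1.20, 0.92, 2.0])


def _random_Q(rng):
    return IntensityMatrix(rng.uniform(0.2, 2.5, size=N_TRANSIENT)).Q


class TestTransitionProbability:
    def test_t_zero_is_identity(self):
        P = transition_probability(IntensityMatrix(RATES).Q, 0.0)
        assert np.allclose(P, np.eye(P.shape[0]))

    def test_two_state_closed_form(self):
        lam = 0.7
        Q = np.array([[-lam, lam], [0.0, 0.0]])
        for t in (0.3, 1.0, 4.0):
            P = transition_probability(Q, t)
            assert P[0, 1] == pytest.approx(1 - math.exp(-lam * t), abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_probability(IntensityMatrix(RATES).Q, -1.0)

    def test_matches_ode_integration(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            Q = _random_Q(rng)
            t = rng.uniform(0.2, 3.0)
            P = transition_probability(Q, t)
            sol = solve_ivp(lambda _, y: (y.reshape(Q.shape) @ Q).ravel(),
                            (0.0, t), np.eye(Q.shape[0]).ravel(),
                            rtol=1e-11, atol=1e-13)
            assert np.abs(P - sol.y[:, -1].reshape(Q.shape)).max() < 1e-8
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_chapman_kolmogorov(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            Q = _random_Q(rng)
            s, t = rng.uniform(0.1, 2.0, size=2)
            lhs = transition_probability(Q, s) @ transition_probability(Q, t)
            assert np.abs(lhs - transition_probability(Q, s + t)).max() < 1e-8

    def test_eigen_fast_path_matches_expm(self):
        rng = np.random.default_rng(2)
        for rates in [rng.uniform(0.2, 2.0, N_TRANSIENT),
                      np.full(N_TRANSIENT, 0.8)]:  # degenerate spectrum
            im = IntensityMatrix(rates)
            dts = rng.uniform(0.1, 4.0, size=40)
            rs = rng.integers(0, N_TRANSIENT, size=40)
            ss = np.minimum(rs + rng.integers(0, 3, size=40), N_TRANSIENT)
            vals = _eig_P_entries(rates, dts, rs, ss)
            ref = np.array([expm(dt * im.Q)[r, s]
                            for dt, r, s in zip(dts, rs, ss)])
            assert np.abs(vals - ref).max() < 1e-6


class TestPanelLikelihood:
    def test_single_pair_closed_form(self):
        lam = RATES[0]
        panels = [PanelSeries(np.array([0.0, 2.0]), np.array([0, 0]))]
        ll = panel_log_likelihood(IntensityMatrix(RATES), panels)
        assert ll == pytest.approx(-lam * 2.0, abs=1e-8)

    def test_empty_panels(self):
        assert panel_log_likelihood(IntensityMatrix(RATES), []) == 0.0

    def test_backward_transition_is_minus_inf(self):
        panels = [PanelSeries(np.array([0.0, 1.0]), np.array([3, 1]))]
        assert panel_log_likelihood(IntensityMatrix(RATES), panels) == -np.inf

    def test_likelihood_peaks_at_truth(self):
        rng = np.random.default_rng(5)
        panels = _simulate_panels(RATES, 400, rng)
        ll_true = panel_log_likelihood(IntensityMatrix(RATES), panels)
        for factor in (0.7, 1.4):
            ll_pert = panel_log_likelihood(IntensityMatrix(RATES * factor), panels)
            assert ll_true > ll_pert


def _simulate_panels(rates, n, rng, gap=2.5):
    """Exact-event chain observed at fixed gaps plus exact absorption at 10."""
    panels = []
    for _ in range(n):
        entries = np.concatenate(
            [[0.0], np.cumsum(rng.exponential(1.0 / rates[:N_TRANSIENT - 1]))])
        t10 = entries[N_TRANSIENT - 1]
        times, states = [0.0], [0]
        t = 0.0
        while True:
            t += gap
            if t >= t10:
                break
            times.append(t)
            states.append(int(np.searchsorted(entries, t, side="right") - 1))
        times.append(t10)
        states.append(N_TRANSIENT - 1)
        panels.append(PanelSeries(np.array(times), np.array(states),
                                  final_exact=True))
    return panels


class TestFit:
    def test_fine_panels_match_occupancy_estimator(self):
        # continuously-observed limit: rate = transitions / time in state
        rng = np.random.default_rng(6)
        panels = _simulate_panels(RATES, 250, rng, gap=0.05)
        fit = fit_intensities(panels)
        time_in, moves = np.zeros(N_TRANSIENT), np.zeros(N_TRANSIENT)
        for p in panels:
            for k in range(len(p.times) - 1):
                time_in[p.states[k]] += p.times[k + 1] - p.times[k]
                if p.states[k + 1] > p.states[k]:
                    moves[p.states[k]] += 1
        occupancy = moves[:N_TRANSIENT - 1] / time_in[:N_TRANSIENT - 1]
        assert np.abs(fit.rates[:N_TRANSIENT - 1] / occupancy - 1).max() < 0.03

    def test_unobserved_rate_flagged(self):
        rng = np.random.default_rng(7)
        panels = _simulate_panels(RATES, 100, rng)
        fit = fit_intensities(panels)
        assert not fit.identifiable[N_TRANSIENT - 1]  # 10 cm -> D: no deliveries
        assert fit.identifiable[: N_TRANSIENT - 1].all()

    def test_cohort_panels_round_trip(self, parity0_cohort):
        panels = records_to_panels(parity0_cohort[:50])
        assert all(np.all(np.diff(p.states) >= 0) for p in panels)
        assert all(p.final_exact and p.states[-1] == state_index(10)
                   for p in panels)


class TestSimulation:
    def test_invalid_args(self):
        im = IntensityMatrix(RATES)
        with pytest.raises(ValueError):
            simulate_markov_cohort(im, {2: 1.0}, n=0)
        with pytest.raises(ValueError):
            simulate_markov_cohort(im, {2: 1.0}, n=10, step_h=0.0)

    def test_single_rate_median_sojourn(self):
        # rate ln2 per hour -> median sojourn 1.0 h, up to grid resolution
        rates = np.geomspace(0.2, 2.0, N_TRANSIENT)
        rates[2] = math.log(2.0)
        traj = simulate_markov_cohort(IntensityMatrix(rates), {2: 1.0},
                                      n=30_000, rng_seed=8)
        tab = markov_sojourn_table(traj)
        row = tab[tab.from_cm == STATE_VALUES[2]]
        assert row.p50.iloc[0] == pytest.approx(1.0, abs=traj.step_h + 1e-9)

    def test_empirical_occupancy_matches_p_t(self):
        im = IntensityMatrix(RATES)
        traj = simulate_markov_cohort(im, {2: 1.0}, n=20_000, rng_seed=9)
        t = 2.0
        k = int(round(t / traj.step_h))
        occupied = (traj.entry_tick <= k) & (traj.entry_tick >= 0)
        state_at_t = occupied.cumsum(axis=1).argmax(axis=1)
        emp = np.bincount(state_at_t, minlength=N_TRANSIENT) / traj.n
        # women at 10 cm stay there in the first-stage simulation: compare
        # transient states only
        P = transition_probability(im.Q, t)[0]
        assert np.abs(emp[:N_TRANSIENT - 1] - P[:N_TRANSIENT - 1]).max() < 0.015

    def test_stalled_chain_hits_horizon(self, caplog):
        rates = np.full(N_TRANSIENT, 1e-4)
        traj = simulate_markov_cohort(IntensityMatrix(rates), {2: 1.0}, n=50,
                                      rng_seed=10, max_hours=10.0)
        assert (traj.entry_tick[:, -1] == -1).all()


@pytest.fixture(scope="module")
def traj():
    return simulate_markov_cohort(
        IntensityMatrix(RATES), {2: 0.3, 3: 0.1, 4: 0.3, 5: 0.15, 6: 0.15},
        n=40_000, rng_seed=11)


class TestTables:

    def test_sojourn_quantiles_match_exponential(self, traj):
        tab = markov_sojourn_table(traj)
        for row in tab.itertuples():
            i = STATE_VALUES.index(row.from_cm)
            for p, val in [(0.05, row.p5), (0.5, row.p50), (0.95, row.p95)]:
                # one grid step of discretisation plus Monte-Carlo noise of
                # the empirical quantile at this admission mix
                mc = 4 * math.sqrt(p * (1 - p) / row.n) / (RATES[i] * (1 - p))
                assert abs(val - (-math.log1p(-p) / RATES[i])) <= traj.step_h + mc

    def test_first_passage_additivity_of_means(self, traj):
        tab = markov_cumulative_table(traj, admissions=(4,))
        sub = tab[(tab.admission_cm == 4)]
        # mean first-passage 4 -> 10 equals the sum of mean sojourns
        i4 = STATE_VALUES.index(4)
        m = (traj.admission_idx == i4) & traj.reached(N_TRANSIENT - 1)
        fp = (traj.entry_tick[m, N_TRANSIENT - 1] - 0) * traj.step_h
        expected = np.sum(1.0 / RATES[i4:N_TRANSIENT - 1])
        assert np.mean(fp) == pytest.approx(expected, rel=0.03)
        assert (sub.to_cm.diff().dropna() > 0).all()
        assert sub.sort_values("to_cm").p50.is_monotonic_increasing

    def test_min_reported_positive_sojourn_is_one_step(self, traj):
        tab = markov_sojourn_table(traj)
        positive = tab[tab.p5 > 0]
        assert (positive.p5 >= traj.step_h - 1e-9).all()

    def test_average_curve_anchored_and_monotone(self, traj):
        curve = average_curve_markov(traj, np.arange(0.0, 8.0, 0.25))
        assert curve.mean_dilatation.iloc[0] == pytest.approx(10.0)
        assert (curve.mean_dilatation.diff().dropna() <= 1e-9).all()


def test_survival_and_markov_agree_on_identifiable_cohort(dense_exam_cohort):
    """On an hourly-examined cohort both models are well informed; their
    mid-labour sojourn medians differ only by the exponential-vs-log-normal
    shape mismatch, within a 30% sanity band (the two models differ by
    design, so this is a band, not equality)."""
    from laborkinetics.reporting import admission_distribution
    from laborkinetics.survival import sojourn_table

    surv = sojourn_table(dense_exam_cohort, parity_label="0")
    Q = fit_intensities(records_to_panels(dense_exam_cohort))
    traj = simulate_markov_cohort(Q, admission_distribution(dense_exam_cohort),
                                  n=20_000, rng_seed=21)
    mk = markov_sojourn_table(traj, parity_label="0")
    for tr in [(4, 5), (5, 6)]:
        s = surv[(surv.from_cm == tr[0]) & (surv.to_cm == tr[1])].p50.iloc[0]
        m = mk[(mk.from_cm == tr[0]) & (mk.to_cm == tr[1])].p50.iloc[0]
        assert abs(m / s - 1) < 0.30, tr
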