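"""Progressive continuous-time Markov model for panel-observed dilatation.

States are the documented dilatation levels 2,3,...,8,10 cm plus an absorbing
delivery state D; the chain is unidirectional (each state can only advance to
the next), so the intensity matrix Q has one free rate per non-absorbing
state.  Exams are panel snapshots whose pairwise likelihood is the matrix
exponential P(t) = exp(tQ); the exactly-recorded arrival at full dilatation
contributes a transition-density term.  Percentile tables are produced by
forward simulation of the fitted chain on a fixed 5-minute grid, mirroring
the way the published Markov columns were obtained (their 5th percentiles
bottom out at 0.08 h = one grid step).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .cohort import LabourRecord

log = logging.getLogger(__name__)

#: dilatation value of each transient state, in order; D is appended last.
STATE_VALUES = (2, 3, 4, 5, 6, 7, 8, 10)
N_TRANSIENT = len(STATE_VALUES)  # 8
N_STATES = N_TRANSIENT + 1  # + absorbing D
DEFAULT_STEP_H = 1.0 / 12.0  # 5-minute simulation grid
_DELIVERY_RATE_DEFAULT = 1.0  # 10 cm -> D rate when no delivery times observed


def state_index(dilatation: int) -> int:
    """Map an exam dilatation to its state index (9 cm is never documented
    and is folded into the 8 cm state)."""
    d = min(max(int(dilatation), 2), 10)
    if d == 9:
        d = 8
    return STATE_VALUES.index(d)


@dataclass
class IntensityMatrix:
    """Transition intensities of the progressive chain.

    ``rates[i]`` is the intensity out of transient state i into state i+1
    (the last one being 10 cm -> D).  ``identifiable`` marks rates actually
    informed by the data; others are held at their initial value.
    """

    rates: np.ndarray  # shape (8,)
    se: np.ndarray | None = None
    identifiable: np.ndarray = field(
        default_factory=lambda: np.ones(N_TRANSIENT, dtype=bool))
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_TRANSIENT,):
            raise ValueError(f"need {N_TRANSIENT} rates")
        if np.any(self.rates < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def Q(self) -> np.ndarray:
        Q = np.zeros((N_STATES, N_STATES))
        for i, q in enumerate(self.rates):
            Q[i, i] = -q
            Q[i, i + 1] = q
        return Q

    def sojourn_quantile(self, i: int, p: float) -> float:
        """Closed-form exponential sojourn quantile -ln(1-p)/q for state i."""
        return -math.log1p(-p) / self.rates[i]


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(tQ); row-stochastic with entries in [0, 1]."""
    if t < 0:
        raise ValueError("time must be >= 0")
    Q = np.asarray(Q, dtype=float)
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("rows of Q must sum to 0")
    P = linalg.expm(t * Q)
    np.clip(P, 0.0, 1.0, out=P)
    return P


# -- likelihood machinery ---------------------------------------------------

@dataclass
class PanelSeries:
    """One woman's snapshot series; the final entry may be an exactly-timed
    arrival (full dilatation), not a snapshot."""

    times: np.ndarray
    states: np.ndarray  # state indices
    final_exact: bool = False


def records_to_panels(records: list[LabourRecord]) -> list[PanelSeries]:
    """Exams become panel snapshots; the recorded full-dilatation time an
    exactly-timed entry into the 10 cm state."""
    panels = []
    for rec in records:
        times, states = [], []
        for t, d in rec.exams:
            s = state_index(d)
            if times and t == times[-1] and s == states[-1]:
                continue
            times.append(t)
            states.append(s)
        final_exact = (rec.full_dilatation_time_h is not None
                       and states and states[-1] == state_index(10)
                       and times[-1] == rec.full_dilatation_time_h)
        panels.append(PanelSeries(np.array(times), np.array(states, dtype=int),
                                  final_exact=final_exact))
    return panels


def _pair_arrays(panels: list[PanelSeries]):
    """Flatten panels into (dt, from, to, exact) transition-pair arrays."""
    dts, rs, ss, exact = [], [], [], []
    for p in panels:
        for k in range(len(p.times) - 1):
            dt = p.times[k + 1] - p.times[k]
            r, s = p.states[k], p.states[k + 1]
            if dt == 0 and r == s:
                continue
            dts.append(dt)
            rs.append(r)
            ss.append(s)
            exact.append(p.final_exact and k == len(p.times) - 2)
    return (np.array(dts), np.array(rs, dtype=int), np.array(ss, dtype=int),
            np.array(exact, dtype=bool))


def _eig_P_entries(rates: np.ndarray, dts: np.ndarray, rs: np.ndarray,
                   ss: np.ndarray) -> np.ndarray:
    """P(dt)[r, s] for many pairs at once via eigendecomposition of Q.

    Q is triangular, so its eigenvalues are {-q_i, 0}; the eigenbasis is
    well-conditioned only when they are separated.  Coincidentally close
    rates are nudged apart by ~1e-5 (negligible for the likelihood); if the
    basis is still ill-conditioned the exact matrix exponential is used for
    each distinct time gap instead.
    """
    q = rates.astype(float)
    scale = max(float(q.max()), 1e-6)
    tol = 1e-5 * scale
    lam_all = np.sort(np.concatenate([q, [0.0]]))
    if np.min(np.diff(lam_all)) < tol:
        # (near-)degenerate spectrum: exact matrix exponential per gap
        Q = IntensityMatrix(q).Q
        uq, inv = np.unique(dts, return_inverse=True)
        mats = np.stack([linalg.expm(dt * Q) for dt in uq])
        return mats[inv, rs, ss]
    im = IntensityMatrix(q)
    w = np.concatenate([-q, [0.0]])
    lam, V = linalg.eig(im.Q)
    V = V.real
    lam = lam.real
    # columns of V follow eig's ordering; match to w by value
    perm = np.argsort(np.argsort(w))
    V = V[:, np.argsort(lam)][:, perm]
    if np.linalg.cond(V) > 1e10:
        uq, inv = np.unique(dts, return_inverse=True)
        mats = np.stack([linalg.expm(dt * im.Q) for dt in uq])
        return mats[inv, rs, ss]
    W = linalg.inv(V)
    # P(dt)[r,s] = sum_m V[r,m] W[m,s] exp(w_m dt)
    A = V[rs, :] * W[:, ss].T  # (npairs, nstates)
    E = np.exp(np.outer(dts, w))
    return np.einsum("km,km->k", A, E)


def panel_log_likelihood(Q: "IntensityMatrix | np.ndarray",
                         panels: list[PanelSeries]) -> float:
    """Sum over snapshot pairs of ln P(dt)[r,s], plus a density term
    ln([P(dt) Q][r, s*]) for each exactly-timed final arrival."""
    im = Q if isinstance(Q, IntensityMatrix) else IntensityMatrix(
        -np.diag(np.asarray(Q))[:N_TRANSIENT])
    dts, rs, ss, exact = _pair_arrays(panels)
    if dts.size == 0:
        return 0.0
    if np.any(ss < rs):
        log.error("impossible backward transition in panels")
        return -np.inf
    return float(_loglik_from_pairs(im.rates, dts, rs, ss, exact))


def _loglik_from_pairs(rates, dts, rs, ss, exact) -> float:
    ll = 0.0
    snap = ~exact
    if np.any(snap):
        p = _eig_P_entries(rates, dts[snap], rs[snap], ss[snap])
        ll += float(np.sum(np.log(np.maximum(p, 1e-300))))
    if np.any(exact):
        # exact entry into s at dt: density = P(dt)[r, s-1] * q_{s-1}
        r_e, s_e, dt_e = rs[exact], ss[exact], dts[exact]
        same = s_e == r_e  # already there at the previous snapshot: no info
        pred = np.maximum(s_e - 1, 0)
        p = _eig_P_entries(rates, dt_e, r_e, pred)
        dens = np.where(same, 1.0, np.maximum(p, 1e-300) * rates[pred])
        ll += float(np.sum(np.log(np.maximum(dens, 1e-300))))
    return ll


def fit_intensities(panels: list[PanelSeries],
                    init: np.ndarray | None = None) -> IntensityMatrix:
    """Maximise the panel likelihood over log-intensities.

    Rates never crossed by any observation pair are flagged non-identifiable
    and held at their initial value (the delivery rate is such whenever no
    delivery times are in the panels).  Standard errors come from the
    numerical Hessian at the optimum.
    """
    dts, rs, ss, exact = _pair_arrays(panels)
    if dts.size == 0:
        raise ValueError("no observation pairs to fit")
    if np.any(ss < rs):
        raise ValueError("impossible backward transition in panels")
    crossed = np.array([np.any((rs <= i) & (ss > i)) for i in range(N_TRANSIENT)])
    if init is None:
        # distinct starting rates keep the eigenbasis well-conditioned
        init = np.geomspace(0.35, 1.4, N_TRANSIENT)
        init[-1] = _DELIVERY_RATE_DEFAULT
    init = np.asarray(init, dtype=float)
    free = crossed.copy()
    theta0 = np.log(init[free])

    def nll(theta: np.ndarray) -> float:
        rates = init.copy()
        rates[free] = np.exp(theta)
        return -_loglik_from_pairs(rates, dts, rs, ss, exact)

    res = optimize.minimize(nll, theta0, method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-12})
    rates = init.copy()
    rates[free] = np.exp(res.x)
    se = np.full(N_TRANSIENT, np.nan)
    try:
        H = _numeric_hessian(nll, res.x)
        cov = np.linalg.inv(H)
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se[free] = rates[free] * se_log
    except np.linalg.LinAlgError:
        log.warning("Hessian not invertible; no standard errors")
    if not crossed.all():
        log.info("non-identifiable rates held at init: %s",
                 [i for i in range(N_TRANSIENT) if not crossed[i]])
    return IntensityMatrix(rates=rates, se=se, identifiable=crossed,
                           loglik=-float(res.fun), converged=bool(res.success))


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    return H


# -- simulation and empirical tables ----------------------------------------

@dataclass
class MarkovTrajectories:
    """Grid simulation of the fitted chain, stored compactly as the tick at
    which each woman first enters each transient state (-1 = never)."""

    entry_tick: np.ndarray  # (n, 8) int
    admission_idx: np.ndarray  # (n,) int
    step_h: float

    @property
    def n(self) -> int:
        return self.entry_tick.shape[0]

    def reached(self, i: int) -> np.ndarray:
        return self.entry_tick[:, i] >= 0


def simulate_markov_cohort(Q: IntensityMatrix,
                           admission_distribution: dict[int, float],
                           n: int,
                           step_h: float = DEFAULT_STEP_H,
                           rng_seed: int | np.random.Generator = 0,
                           max_hours: float = 96.0) -> MarkovTrajectories:
    """Advance each woman on a fixed grid with one-step probabilities
    P(step); states skipped within one step get zero sojourn.  Admission
    states are drawn from ``admission_distribution`` over dilatation cm."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if step_h <= 0:
        raise ValueError("step must be > 0")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    levels = sorted(admission_distribution)
    probs = np.array([admission_distribution[d] for d in levels], dtype=float)
    probs = probs / probs.sum()
    adm_idx = np.array([state_index(d) for d in levels])
    admission = rng.choice(adm_idx, size=n, p=probs)

    P = transition_probability(IntensityMatrix(Q.rates).Q, step_h)
    last = N_TRANSIENT - 1  # 10 cm: terminal for first-stage simulation
    cumP = np.cumsum(P[:, :N_TRANSIENT], axis=1)
    cumP[:, -1] = 1.0

    entry = np.full((n, N_TRANSIENT), -1, dtype=np.int64)
    entry[np.arange(n), admission] = 0
    cur = admission.copy()
    active = np.flatnonzero(cur < last)
    max_ticks = int(np.ceil(max_hours / step_h))
    tick = 0
    while active.size and tick < max_ticks:
        tick += 1
        u = rng.random(active.size)
        nxt = cur[active].copy()
        for s in np.unique(cur[active]):
            m = cur[active] == s
            nxt[m] = np.searchsorted(cumP[s], u[m], side="right")
        moved = nxt > cur[active]
        if np.any(moved):
            idx = active[moved]
            for s in range(1, N_TRANSIENT):
                newly = (nxt[moved] >= s) & (cur[idx] < s)
                entry[idx[newly], s] = tick
            cur[idx] = nxt[moved]
        active = active[nxt < last]
    if active.size:
        log.warning("%d trajectories hit the %g h horizon before 10 cm",
                    active.size, max_hours)
    return MarkovTrajectories(entry_tick=entry, admission_idx=admission,
                              step_h=step_h)


def _percentiles(x: np.ndarray, probs=(0.05, 0.5, 0.95)) -> list[float]:
    return [float(np.percentile(x, 100 * p)) for p in probs]


def markov_sojourn_table(traj: MarkovTrajectories,
                         parity_label: str | None = None,
                         probs=(0.05, 0.5, 0.95)) -> pd.DataFrame:
    """Empirical sojourn percentiles per transition, at grid resolution."""
    rows = []
    for i in range(N_TRANSIENT - 1):
        m = traj.reached(i) & traj.reached(i + 1)
        if not np.any(m):
            continue
        soj = (traj.entry_tick[m, i + 1] - traj.entry_tick[m, i]) * traj.step_h
        p5, p50, p95 = _percentiles(soj, probs)
        rows.append((parity_label, STATE_VALUES[i], STATE_VALUES[i + 1],
                     int(m.sum()), p5, p50, p95))
    return pd.DataFrame(
        rows, columns=["parity", "from_cm", "to_cm", "n", "p5", "p50", "p95"])


def markov_cumulative_table(traj: MarkovTrajectories,
                            parity_label: str | None = None,
                            admissions=(3, 4, 5, 6),
                            probs=(0.05, 0.5, 0.95)) -> pd.DataFrame:
    """Empirical first-passage percentiles from each admission state to each
    later level."""
    rows = []
    for adm in admissions:
        ia = state_index(adm)
        base = traj.admission_idx == ia
        for i in range(ia + 1, N_TRANSIENT):
            m = base & traj.reached(i)
            if not np.any(m):
                continue
            fp = (traj.entry_tick[m, i] - traj.entry_tick[m, ia]) * traj.step_h
            p5, p50, p95 = _percentiles(fp, probs)
            rows.append((parity_label, adm, STATE_VALUES[i], int(m.sum()),
                         p5, p50, p95))
    return pd.DataFrame(
        rows,
        columns=["parity", "admission_cm", "to_cm", "n", "p5", "p50", "p95"])


def average_curve_markov(traj: MarkovTrajectories,
                         tau_grid: np.ndarray) -> pd.DataFrame:
    """Average dilatation at each reversed time tau (hours before reaching
    full dilatation), over trajectories still in labour at that tau; the
    curve is anchored at exactly 10 cm at tau = 0."""
    i10 = N_TRANSIENT - 1
    ok = traj.reached(i10)
    entry_h = traj.entry_tick[ok].astype(float) * traj.step_h
    t10 = entry_h[:, i10]
    values = np.array(STATE_VALUES, dtype=float)
    rows = []
    for tau in np.asarray(tau_grid, dtype=float):
        m = t10 >= tau
        if not np.any(m):
            continue
        u = (t10[m] - tau)[:, None]
        entered = (traj.entry_tick[ok][m] >= 0) & (entry_h[m] <= u + 1e-12)
        state_val = np.where(entered, values[None, :], -np.inf).max(axis=1)
        rows.append((tau, float(state_val.mean()), int(m.sum())))
    return pd.DataFrame(rows, columns=["tau_h", "mean_dilatation", "n"])
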