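"""Interval-censored log-normal survival analysis of labour progression.

Sparse exams bracket the time each integer dilatation is first reached;
differences of those brackets bound each 1-cm sojourn.  Durations are modelled
as log-normal and fitted by maximum likelihood over exact, interval-censored
and left-censored observations jointly, after which medians and outer
percentiles are read off the fitted quantile function — per transition
(sojourn tables) and per admission stratum (cumulative-duration tables and
their 95th-percentile "staircase" thresholds).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import LabourRecord
from .synthetic import LEVELS
from .calibration import TRANSITIONS

log = logging.getLogger(__name__)

_LOG_EPS = 1e-300


@dataclass(frozen=True)
class ReachingInterval:
    """Bracket on the time (since admission) a dilatation level is reached."""

    dilatation: int
    lower: float
    upper: float
    exact: bool


@dataclass(frozen=True)
class IntervalDatum:
    """One duration observation: exact, interval- or left/right-censored."""

    lower: float
    upper: float  # may be +inf (right-censored)
    exact: bool
    woman_id: str = ""


@dataclass
class LogNormalFit:
    mu: float
    sigma: float
    loglik: float
    n_exact: int
    n_interval: int
    converged: bool

    def percentile(self, p: float) -> float:
        return lognormal_percentiles(self, (p,))[0]


def reaching_intervals(record: LabourRecord) -> dict[int, ReachingInterval]:
    """Bracket the reaching time of every modelled level from the exam series.

    The admission level itself is treated as reached exactly at time 0; for
    each later level the bracket is (last exam below it, first exam at or
    above it]; full dilatation is exact when its time is recorded.  A record
    whose exam dilatations regress is rejected as an outlier.
    """
    dil = [d for _, d in record.exams]
    if any(b < a for a, b in zip(dil, dil[1:])):
        raise ValueError(f"{record.woman_id}: regressing dilatations")
    exams = list(record.exams)
    if record.full_dilatation_time_h is not None and exams[-1][1] < 10:
        # the recorded full-dilatation time acts as a final assessment
        exams.append((record.full_dilatation_time_h, 10))
    adm = record.admission_dilatation
    out: dict[int, ReachingInterval] = {}
    if adm in LEVELS:
        out[adm] = ReachingInterval(adm, 0.0, 0.0, True)
    for d in LEVELS:
        if d <= adm:
            continue
        below = [t for t, x in exams if x < d]
        at_or_above = [t for t, x in exams if x >= d]
        if not at_or_above:
            continue  # never observed reaching d (no recorded 10 cm either)
        lower = max(below) if below else 0.0
        upper = min(at_or_above)
        if d == 10 and record.full_dilatation_time_h is not None:
            t10 = record.full_dilatation_time_h
            out[d] = ReachingInterval(d, t10, t10, True)
        else:
            out[d] = ReachingInterval(d, lower, upper, upper == lower)
    return out


def sojourn_data(records: list[LabourRecord], transition: tuple[int, int],
                 ) -> list[IntervalDatum]:
    """Per-woman bounds on the sojourn of one transition d -> d'.

    Combining the two reaching brackets conservatively gives
    [max(0, L' - U), U' - L]; the datum is exact when both reaching times are.
    Women admitted above d never expose the transition and are excluded.
    """
    d, d_next = transition
    if transition not in TRANSITIONS and transition != (2, 3):
        raise ValueError(f"unknown transition {transition}")
    data: list[IntervalDatum] = []
    for rec in records:
        if rec.admission_dilatation > d:
            continue
        try:
            reach = reaching_intervals(rec)
        except ValueError:
            continue
        if d not in reach or d_next not in reach:
            continue
        a, b = reach[d], reach[d_next]
        if a.exact and b.exact:
            t = b.lower - a.lower
            data.append(IntervalDatum(t, t, True, rec.woman_id))
        else:
            lo = max(0.0, b.lower - a.upper)
            hi = b.upper - a.lower
            data.append(IntervalDatum(lo, hi, False, rec.woman_id))
    return data


@dataclass(frozen=True)
class SojournBrackets:
    """The two reaching brackets behind one sojourn observation."""

    ref_lower: float
    ref_upper: float
    tgt_lower: float
    tgt_upper: float
    ref_exact: bool
    tgt_exact: bool
    woman_id: str = ""


def sojourn_pair_data(records: list[LabourRecord], transition: tuple[int, int],
                      ) -> list[SojournBrackets]:
    """Paired reaching brackets for one transition, keeping the origin and
    target uncertainty separate (richer than the conservative single
    interval of :func:`sojourn_data`)."""
    d, d_next = transition
    pairs: list[SojournBrackets] = []
    for rec in records:
        if rec.admission_dilatation > d:
            continue
        try:
            reach = reaching_intervals(rec)
        except ValueError:
            continue
        if d not in reach or d_next not in reach:
            continue
        a, b = reach[d], reach[d_next]
        pairs.append(SojournBrackets(a.lower, a.upper, b.lower, b.upper,
                                     a.exact, b.exact, rec.woman_id))
    return pairs


_GL_X, _GL_W = np.polynomial.legendre.leggauss(16)


class _BracketArrays:
    """Pre-grouped arrays for the latent-origin-integrated likelihood."""

    def __init__(self, pairs: list[SojournBrackets]):
        ee, re_, ri_te, ri_ti = [], [], [], []
        for p in pairs:
            if p.ref_exact and p.tgt_exact:
                ee.append(max(p.tgt_lower - p.ref_lower, 1e-6))
            elif p.ref_exact:
                re_.append((max(p.tgt_lower - p.ref_lower, 0.0),
                            p.tgt_upper - p.ref_lower))
            elif p.tgt_exact:
                ri_te.append((p.ref_lower, p.ref_upper, p.tgt_lower))
            else:
                ri_ti.append((p.ref_lower, p.ref_upper, p.tgt_lower, p.tgt_upper))
        self.log_t_ee = np.log(np.array(ee)) if ee else np.empty(0)
        if re_:
            arr = np.array(re_)
            self.re_lo, self.re_hi = arr[:, 0], arr[:, 1]
        else:
            self.re_lo = self.re_hi = np.empty(0)

        def nodes(L, U):
            half = 0.5 * (U - L)
            return half[:, None] * _GL_X[None, :] + 0.5 * (U + L)[:, None]

        if ri_te:
            arr = np.array(ri_te)
            self.te_u = nodes(arr[:, 0], arr[:, 1])
            self.te_t = np.maximum(arr[:, 2][:, None] - self.te_u, 1e-12)
        else:
            self.te_t = np.empty((0, _GL_X.size))
        if ri_ti:
            arr = np.array(ri_ti)
            u = nodes(arr[:, 0], arr[:, 1])
            self.ti_hi = arr[:, 3][:, None] - u
            self.ti_lo = np.maximum(arr[:, 2][:, None] - u, 0.0)
        else:
            self.ti_hi = self.ti_lo = np.empty((0, _GL_X.size))
        self.n = len(pairs)
        self.n_exact = len(ee)

    def neg_loglik(self, theta: np.ndarray) -> float:
        mu, logsig = theta
        sigma = math.exp(logsig)

        def cdf(x):
            return np.where(
                x <= 0.0, 0.0,
                stats.norm.cdf((np.log(np.maximum(x, 1e-12)) - mu) / sigma))

        ll = 0.0
        if self.log_t_ee.size:
            z = (self.log_t_ee - mu) / sigma
            ll += float(np.sum(-0.5 * z * z - 0.5 * math.log(2 * math.pi)
                               - self.log_t_ee - logsig))
        if self.re_lo.size:
            ll += float(np.sum(np.log(np.maximum(
                cdf(self.re_hi) - cdf(self.re_lo), _LOG_EPS))))
        if self.te_t.size:
            z = (np.log(self.te_t) - mu) / sigma
            dens = np.exp(-0.5 * z * z) / (math.sqrt(2 * math.pi) * self.te_t * sigma)
            p = 0.5 * dens @ _GL_W
            ll += float(np.sum(np.log(np.maximum(p, _LOG_EPS))))
        if self.ti_hi.size:
            p = 0.5 * (cdf(self.ti_hi) - cdf(self.ti_lo)) @ _GL_W
            ll += float(np.sum(np.log(np.maximum(p, _LOG_EPS))))
        return -ll


def fit_lognormal_brackets(pairs: list[SojournBrackets],
                           min_n: int = 10) -> LogNormalFit:
    """Log-normal sojourn MLE integrating over the latent origin time.

    Each woman contributes the probability of her observed bracket pattern
    with the unknown origin (time the lower level was reached) integrated
    uniformly over its own bracket — far tighter than collapsing the pair to
    one conservative interval, which attenuates transitions much faster than
    the exam spacing.
    """
    if len(pairs) < min_n:
        raise ValueError(f"need >= {min_n} sojourn observations, got {len(pairs)}")
    arrays = _BracketArrays(pairs)
    mids = [math.log(max(0.5 * (p.tgt_lower + p.tgt_upper)
                         - 0.5 * (p.ref_lower + p.ref_upper), 5e-2))
            for p in pairs]
    mu0, sd0 = float(np.mean(mids)), max(float(np.std(mids)), 0.3)
    best = None
    for x0 in [(mu0, math.log(sd0)), (mu0 + 0.5, math.log(sd0 * 1.5)),
               (mu0 - 0.5, math.log(max(sd0 * 0.6, 0.2)))]:
        res = optimize.minimize(
            arrays.neg_loglik, np.array(x0), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mu, logsig = best.x
    return LogNormalFit(mu=float(mu), sigma=float(math.exp(logsig)),
                        loglik=-float(best.fun), n_exact=arrays.n_exact,
                        n_interval=arrays.n - arrays.n_exact,
                        converged=bool(best.success))


def _neg_loglik(theta: np.ndarray, logt: np.ndarray, lo: np.ndarray,
                hi: np.ndarray) -> float:
    mu, logsig = theta
    sigma = math.exp(logsig)
    ll = 0.0
    if logt.size:
        z = (logt - mu) / sigma
        ll += float(np.sum(-0.5 * z * z - 0.5 * math.log(2 * math.pi)
                           - logt - logsig))
    if lo.size:
        zu = np.where(np.isinf(hi), np.inf, (np.log(np.maximum(hi, _LOG_EPS)) - mu) / sigma)
        cu = np.where(np.isinf(hi), 1.0, stats.norm.cdf(zu))
        cl = np.where(lo <= 0.0, 0.0, stats.norm.cdf((np.log(np.maximum(lo, _LOG_EPS)) - mu) / sigma))
        ll += float(np.sum(np.log(np.maximum(cu - cl, _LOG_EPS))))
    return -ll


def fit_lognormal(data: list[IntervalDatum], min_n: int = 10) -> LogNormalFit:
    """Maximum-likelihood log-normal fit to mixed exact/censored durations.

    Exact observations contribute the log-normal density; censored ones the
    probability mass between their bounds, with a zero lower bound handled as
    left-censoring.  Optimised over (mu, ln sigma) with multistart from
    log-midpoint moments; with only exact data the estimate coincides with
    the closed-form mean/SD of the log durations.
    """
    informative = [x for x in data if x.exact or np.isfinite(x.upper)
                   or x.lower > 0]
    if len(informative) < min_n:
        raise ValueError(f"need >= {min_n} informative durations, "
                         f"got {len(informative)}")
    exact_t = np.array([max(x.lower, 1e-6) for x in data if x.exact])
    iv = [x for x in data if not x.exact]
    lo = np.array([x.lower for x in iv])
    hi = np.array([x.upper for x in iv])
    logt = np.log(exact_t)

    if iv:
        mid = np.where(np.isinf(hi), lo * 2 + 1.0, np.maximum((lo + hi) / 2, 1e-3))
        pooled = np.concatenate([logt, np.log(mid)])
    else:
        pooled = logt
        if np.allclose(pooled, pooled[0]):
            raise ValueError("degenerate all-equal exact data (sigma -> 0)")
    mu0 = float(np.mean(pooled))
    sd0 = float(np.std(pooled))
    sd0 = max(sd0, 0.2)
    starts = [(mu0, math.log(sd0)),
              (mu0 + 0.5, math.log(sd0 * 1.5)),
              (mu0 - 0.5, math.log(max(sd0 * 0.5, 0.1)))]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik, np.array(x0), args=(logt, lo, hi),
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-8, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    mu, logsig = best.x
    return LogNormalFit(mu=float(mu), sigma=float(math.exp(logsig)),
                        loglik=-float(best.fun), n_exact=len(exact_t),
                        n_interval=len(iv),
                        converged=bool(best.success or best.fun < np.inf))


def lognormal_percentiles(fit: LogNormalFit, probs=(0.05, 0.5, 0.95)) -> list[float]:
    """Quantiles exp(mu + sigma z_p) of a fitted log-normal, in hours."""
    out = []
    for p in probs:
        if not 0.0 < p < 1.0:
            raise ValueError(f"probability {p} outside (0, 1)")
        out.append(float(np.exp(fit.mu + fit.sigma * stats.norm.ppf(p))))
    return out


def sojourn_table(records: list[LabourRecord], parity_label: str | None = None,
                  probs=(0.05, 0.5, 0.95), min_n: int = 10) -> pd.DataFrame:
    """Per-transition log-normal percentile summary (sojourn-time table)."""
    rows = []
    for tr in TRANSITIONS:
        pairs = sojourn_pair_data(records, tr)
        try:
            fit = fit_lognormal_brackets(pairs, min_n=min_n)
        except ValueError as err:
            log.warning("transition %s skipped: %s", tr, err)
            continue
        p5, p50, p95 = lognormal_percentiles(fit, probs)
        rows.append((parity_label, tr[0], tr[1], len(pairs), p5, p50, p95))
    return pd.DataFrame(
        rows, columns=["parity", "from_cm", "to_cm", "n", "p5", "p50", "p95"])


def admission_to_level_data(records: list[LabourRecord], admission: int,
                            level: int) -> list[IntervalDatum]:
    """Cumulative admission-to-level durations for one admission stratum
    (admission itself is exact at time 0, so the reaching bracket of the
    target level is the duration bracket)."""
    data: list[IntervalDatum] = []
    for rec in records:
        if rec.admission_dilatation != admission:
            continue
        try:
            reach = reaching_intervals(rec)
        except ValueError:
            continue
        if level not in reach:
            continue
        r = reach[level]
        data.append(IntervalDatum(r.lower, r.upper, r.exact, rec.woman_id))
    return data


def cumulative_duration_table(records: list[LabourRecord],
                              parity_label: str | None = None,
                              admissions=(3, 4, 5, 6),
                              probs=(0.05, 0.5, 0.95),
                              min_n: int = 10) -> pd.DataFrame:
    """Cumulative duration of labour from admission dilatation to each later
    level, per admission stratum, as log-normal percentiles."""
    rows = []
    for adm in admissions:
        stratum_n = sum(1 for r in records if r.admission_dilatation == adm)
        for level in [d for d in LEVELS if d > adm]:
            data = admission_to_level_data(records, adm, level)
            try:
                fit = fit_lognormal(data, min_n=min_n)
            except ValueError as err:
                log.warning("admission %d -> %d skipped: %s", adm, level, err)
                continue
            p5, p50, p95 = lognormal_percentiles(fit, probs)
            rows.append((parity_label, adm, level, stratum_n, p5, p50, p95))
    return pd.DataFrame(
        rows,
        columns=["parity", "admission_cm", "to_cm", "n", "p5", "p50", "p95"])


def staircase_series(table: pd.DataFrame, admission_level: int,
                     prob: float = 0.95) -> list[tuple[int, float]]:
    """Ordered (level, hours) steps of one admission stratum's cumulative
    percentile — the protracted-labour threshold line."""
    col = {0.05: "p5", 0.5: "p50", 0.95: "p95"}.get(prob)
    if col is None:
        raise ValueError("prob must be one of 0.05, 0.5, 0.95")
    sub = table[table["admission_cm"] == admission_level].sort_values("to_cm")
    if sub.empty:
        raise ValueError(f"no rows for admission level {admission_level}")
    # per-level fits of nested durations are monotone up to estimation noise;
    # a running max guarantees the step-function contract
    hours = np.maximum.accumulate([float(getattr(r, col)) for r in sub.itertuples()])
    return [(int(r.to_cm), h) for r, h in zip(sub.itertuples(), hours)]
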