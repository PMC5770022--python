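"""Three-parameter logistic growth mixed model for average labour curves.

Dilatation observations are anchored in reverse time at full dilatation
(t = 0 at 10 cm, negative before it) and modelled as

    y_ij = beta0 + beta1 / (1 + exp(-(t_ij - (beta2 + b_i)))) + eps_ij,

with a woman-level random shift b_i ~ N(0, sigma_b^2) of the inflection point
and residual noise eps_ij ~ N(0, sigma_eps^2).  The marginal likelihood
integrates b out by adaptive Gauss-Hermite quadrature (Laplace-recentred,
21 nodes by default).  Fitting happens on the signed axis; the reflected
positive axis of the published displays is presentation-only.

The partograph alert-line comparison (1 cm/hour from 4 cm) also lives here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import LabourRecord

log = logging.getLogger(__name__)


@dataclass
class LogisticCurveParams:
    beta0: float  # cm, value as t -> -inf
    beta1: float  # cm, asymptotic height
    beta2: float  # hours (signed axis), inflection point
    sigma_b: float  # hours, SD of the random inflection shift
    sigma_eps: float  # cm, residual SD
    loglik: float = float("nan")
    se: dict = field(default_factory=dict)
    converged: bool = True
    n_women: int = 0

    def validate(self) -> None:
        if self.beta1 <= 0 or self.sigma_eps <= 0 or self.sigma_b < 0:
            raise ValueError("beta1 > 0, sigma_eps > 0, sigma_b >= 0 required")


def logistic_mean(params: LogisticCurveParams, t, b: float = 0.0):
    """Model mean beta0 + beta1/(1 + exp(-(t - (beta2 + b)))) on the signed
    axis; at t = beta2 + b the curve reaches half its height."""
    z = np.asarray(t, dtype=float) - (params.beta2 + b)
    return params.beta0 + params.beta1 * _sigmoid(np.atleast_1d(z)).reshape(z.shape)


def reverse_time(record: LabourRecord) -> pd.DataFrame:
    """Anchor one woman's exams at full dilatation.

    Columns: ``t_signed`` (exam time minus full-dilatation time, <= 0),
    ``t_reversed`` (its reflection, hours before full dilatation) and ``y``.
    The anchor point (0, 10 cm) is appended.  The transform preserves elapsed
    time between exams and is invertible given the anchor time.
    """
    if record.full_dilatation_time_h is None:
        raise ValueError(f"{record.woman_id}: no full-dilatation time to anchor")
    t10 = record.full_dilatation_time_h
    rows = [(record.woman_id, t - t10, t10 - t, float(d))
            for t, d in record.exams if t < t10]
    rows.append((record.woman_id, 0.0, 0.0, 10.0))
    return pd.DataFrame(rows, columns=["woman_id", "t_signed", "t_reversed", "y"])


def cohort_observations(records: list[LabourRecord]) -> pd.DataFrame:
    """Stack reverse-time observation points for a cohort."""
    frames = [reverse_time(r) for r in records
              if r.full_dilatation_time_h is not None]
    if not frames:
        return pd.DataFrame(columns=["woman_id", "t_signed", "t_reversed", "y"])
    return pd.concat(frames, ignore_index=True)


# -- marginal likelihood via adaptive Gauss-Hermite --------------------------

class _ObsLayout:
    """Flat per-observation arrays with woman boundaries for reduceat sums."""

    def __init__(self, obs: pd.DataFrame):
        obs = obs.sort_values("woman_id", kind="stable")
        self.t = obs["t_signed"].to_numpy(dtype=float)
        self.y = obs["y"].to_numpy(dtype=float)
        ids = obs["woman_id"].to_numpy()
        change = np.r_[True, ids[1:] != ids[:-1]]
        self.starts = np.flatnonzero(change)
        self.n_women = self.starts.size
        self.woman_of = np.cumsum(change) - 1
        counts = np.diff(np.r_[self.starts, ids.size])
        self.counts = counts

    def wsum(self, x: np.ndarray) -> np.ndarray:
        return np.add.reduceat(x, self.starts)


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _log_integrand_terms(lay: _ObsLayout, beta0, beta1, beta2, sig_e, b_per_obs):
    z = lay.t - beta2 - b_per_obs
    s = _sigmoid(z)
    r = lay.y - (beta0 + beta1 * s)
    return s, r


def _loglik_agq(theta: np.ndarray, lay: _ObsLayout, gh_x: np.ndarray,
                gh_w: np.ndarray) -> float:
    beta0, beta1, beta2, log_sb, log_se = theta
    # numerical floors: a collapsing random effect is reported by the caller,
    # not chased to exp(-inf)
    sb = max(math.exp(log_sb), 1e-6)
    se_ = max(math.exp(log_se), 1e-6)
    inv_se2, inv_sb2 = 1.0 / se_**2, 1.0 / sb**2

    def log_g(b_vec: np.ndarray) -> np.ndarray:
        bb = b_vec[lay.woman_of]
        _, r = _log_integrand_terms(lay, beta0, beta1, beta2, se_, bb)
        quad = lay.wsum(r * r)
        return (-0.5 * inv_se2 * quad
                - lay.counts * (math.log(se_) + 0.5 * math.log(2 * math.pi))
                - 0.5 * b_vec**2 * inv_sb2
                - math.log(sb) - 0.5 * math.log(2 * math.pi))

    def derivs(b_vec: np.ndarray):
        bb = b_vec[lay.woman_of]
        s, r = _log_integrand_terms(lay, beta0, beta1, beta2, se_, bb)
        sp = s * (1.0 - s)
        dfdb = -beta1 * sp
        d2fdb2 = beta1 * sp * (1.0 - 2.0 * s)
        g1 = inv_se2 * lay.wsum(r * dfdb) - b_vec * inv_sb2
        g2 = inv_se2 * lay.wsum(-dfdb**2 + r * d2fdb2) - inv_sb2
        return g1, g2

    # Laplace step: coarse grid for a global start (the integrand can be far
    # from quadratic in b), then ascent-guarded damped Newton per woman
    grid = np.linspace(-5.0 * sb, 5.0 * sb, 25)
    b = np.zeros(lay.n_women)
    g_best = log_g(b)
    for bg in grid:
        cand = np.full(lay.n_women, bg)
        g_cand = log_g(cand)
        better = g_cand > g_best
        b[better] = bg
        g_best = np.where(better, g_cand, g_best)
    for _ in range(30):
        g1, g2 = derivs(b)
        step = -g1 / np.minimum(g2, -1e-8)
        np.clip(step, -2.0 * sb, 2.0 * sb, out=step)
        factor = np.ones(lay.n_women)
        for _ in range(6):  # backtrack where the step is not an ascent
            b_new = b + factor * step
            g_new = log_g(b_new)
            worse = g_new < g_best - 1e-12
            if not np.any(worse):
                break
            factor[worse] *= 0.5
        improved = g_new >= g_best
        b = np.where(improved, b_new, b)
        g_best = np.where(improved, g_new, g_best)
        if np.max(np.abs(factor * step * improved)) < 1e-10:
            break
    _, g2 = derivs(b)
    g2 = np.minimum(g2, -1.0 / (100.0 * sb * sb))
    sig_hat = 1.0 / np.sqrt(-g2)
    g_mode = g_best

    def quadrature(center: np.ndarray, scale: np.ndarray):
        """Per-woman log integral estimate (relative to g_mode) + moments."""
        acc = np.zeros(lay.n_women)
        m1 = np.zeros(lay.n_women)
        m2 = np.zeros(lay.n_women)
        for xk, wk in zip(gh_x, gh_w):
            bk = center + math.sqrt(2.0) * scale * xk
            om = wk * np.exp(xk * xk + np.clip(log_g(bk) - g_mode, -700, 50))
            acc += om
            m1 += om * bk
            m2 += om * bk * bk
        li = np.log(math.sqrt(2.0)) + np.log(scale) + np.log(np.maximum(acc, 1e-300))
        ok = acc > 1e-250
        mean = np.where(ok, m1 / np.maximum(acc, 1e-300), center)
        var = np.where(ok, m2 / np.maximum(acc, 1e-300) - mean**2, scale**2)
        return li, mean, var

    # Women whose plateau observations leave b identified only one-sidedly
    # have wide integrands for which the narrow Laplace scale undercovers;
    # start those from the prior width instead, then refine everyone once
    # with a moment-matched proposal.
    scale0 = np.where(sig_hat > 0.9 * sb, np.maximum(sig_hat, sb), sig_hat)
    _, mean0, var0 = quadrature(b, scale0)
    scale1 = np.sqrt(np.clip(var0, (0.05 * np.minimum(sig_hat, sb)) ** 2,
                             (20.0 * sb) ** 2))
    li, _, _ = quadrature(mean0, scale1)
    return float(np.sum(g_mode + li))


def fit_pooled_logistic(obs: pd.DataFrame,
                        init=(0.0, 10.0, -3.0)) -> LogisticCurveParams:
    """Nonlinear least squares on pooled points (the sigma_b = 0 limit)."""
    t = obs["t_signed"].to_numpy(dtype=float)
    y = obs["y"].to_numpy(dtype=float)

    def resid(p):
        return y - (p[0] + p[1] * _sigmoid(t - p[2]))

    sol = optimize.least_squares(resid, np.array(init), xtol=1e-14, ftol=1e-14)
    r = resid(sol.x)
    sig_e = math.sqrt(float(np.mean(r * r)))
    n = y.size
    ll = -0.5 * n * (math.log(2 * math.pi * sig_e**2) + 1.0)
    return LogisticCurveParams(*sol.x, sigma_b=0.0, sigma_eps=sig_e,
                               loglik=ll, converged=sol.success,
                               n_women=obs["woman_id"].nunique())


def fit_logistic_nlmm(obs: pd.DataFrame, n_quad: int = 21,
                      init: LogisticCurveParams | None = None,
                      min_women: int = 30) -> LogisticCurveParams:
    """Maximum marginal likelihood fit of the logistic growth mixed model.

    beta0 and beta1 are fixed effects; the inflection point carries the
    normal random shift b_i, integrated out per woman by adaptive
    Gauss-Hermite quadrature.  Standard errors come from the numerical
    Hessian on the natural scale; a sigma_b collapsing towards zero is
    reported as such, not clipped.
    """
    counts = obs.groupby("woman_id").size()
    if (counts >= 2).sum() < min_women:
        raise ValueError(f"need >= {min_women} women with >= 2 points")
    lay = _ObsLayout(obs)
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_quad)
    median_span = float(np.median(-obs.groupby("woman_id")["t_signed"].min()))
    if init is not None:
        starts = [init]
    else:
        # the (beta1, beta2) surface has a near-linear ridge; start from the
        # pooled least-squares solution when it is non-degenerate plus two
        # anchored heuristics, and keep the best optimum
        starts = [LogisticCurveParams(0.0, 10.0, -0.5 * median_span, 1.0, 0.5),
                  LogisticCurveParams(0.0, 10.5, -0.25 * median_span, 1.0, 1.0)]
        try:
            pooled = fit_pooled_logistic(obs, init=(0.0, 10.0, -0.5 * median_span))
            if pooled.converged and 5.0 < pooled.beta1 < 20.0:
                starts.insert(0, LogisticCurveParams(
                    pooled.beta0, pooled.beta1, pooled.beta2, 1.0,
                    max(pooled.sigma_eps * 0.8, 0.05)))
        except Exception:  # pragma: no cover - defensive
            pass

    def nll(theta):
        return -_loglik_agq(theta, lay, gh_x, gh_w)

    res = None
    for start in starts:
        theta0 = np.array([start.beta0, start.beta1, start.beta2,
                           math.log(max(start.sigma_b, 1e-3)),
                           math.log(start.sigma_eps)])
        cand = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                 options={"xatol": 1e-7, "fatol": 1e-9,
                                          "maxiter": 2000, "maxfev": 2500})
        if res is None or cand.fun < res.fun:
            res = cand
    b0, b1, b2, lsb, lse = res.x
    params = LogisticCurveParams(
        beta0=float(b0), beta1=float(b1), beta2=float(b2),
        sigma_b=float(math.exp(lsb)), sigma_eps=float(math.exp(lse)),
        loglik=-float(res.fun), converged=bool(res.success),
        n_women=lay.n_women)
    if params.sigma_b < 1e-3:
        log.warning("sigma_b at boundary (%.2g h): random effect collapsing",
                    params.sigma_b)
    params.se = _natural_scale_se(nll, res.x)
    return params


def _natural_scale_se(nll, theta_hat: np.ndarray) -> dict:
    names = ["beta0", "beta1", "beta2", "sigma_b", "sigma_eps"]

    def nll_nat(p):
        return nll(np.array([p[0], p[1], p[2],
                             math.log(max(p[3], 1e-8)),
                             math.log(max(p[4], 1e-8))]))

    p_hat = np.array([theta_hat[0], theta_hat[1], theta_hat[2],
                      math.exp(theta_hat[3]), math.exp(theta_hat[4])])
    h = np.maximum(1e-4, 1e-4 * np.abs(p_hat))
    n = p_hat.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                nll_nat(p_hat + ei + ej) - nll_nat(p_hat + ei - ej)
                - nll_nat(p_hat - ei + ej) + nll_nat(p_hat - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return dict(zip(names, se.tolist()))
    except np.linalg.LinAlgError:
        log.warning("Hessian not invertible; no standard errors")
        return {}


def average_curve_logistic(params: LogisticCurveParams, grid: np.ndarray,
                           observed_range: tuple[float, float],
                           allow_extrapolation: bool = False) -> pd.DataFrame:
    """Population curve (b = 0) on the signed axis over the observed time
    range only; flags an inflection point falling outside that range."""
    params.validate()
    grid = np.asarray(grid, dtype=float)
    lo, hi = observed_range
    if not allow_extrapolation:
        if np.any(grid < lo - 1e-9) or np.any(grid > hi + 1e-9):
            raise ValueError("grid extends beyond the observed time range")
    out = pd.DataFrame({
        "t_signed": grid,
        "t_reversed": -grid,
        "dilatation": logistic_mean(params, grid),
    })
    out.attrs["inflection_outside_observed_range"] = not (lo <= params.beta2 <= hi)
    return out


def simulate_logistic_observations(params: LogisticCurveParams, n_women: int,
                                   rng: np.random.Generator,
                                   t_range: tuple[float, float] = (-10.0, 0.0),
                                   n_obs_range: tuple[int, int] = (3, 6),
                                   ) -> pd.DataFrame:
    """Draw observation points from the mixed model itself (for parameter-
    recovery studies); every woman gets an anchor-region point near t = 0."""
    rows = []
    lo, hi = t_range
    for i in range(n_women):
        b = rng.normal(0.0, params.sigma_b)
        k = int(rng.integers(n_obs_range[0], n_obs_range[1] + 1))
        ts = np.sort(rng.uniform(lo, hi, size=k))
        ts[-1] = hi  # anchor
        for t in ts:
            y = float(logistic_mean(params, t, b=b)
                      + rng.normal(0.0, params.sigma_eps))
            rows.append((f"s{i:05d}", float(t), -float(t), y))
    return pd.DataFrame(rows, columns=["woman_id", "t_signed", "t_reversed", "y"])


def alert_line_crossing(records: list[LabourRecord], start_dilatation: int = 4,
                        rate_cm_per_h: float = 1.0) -> dict[str, float]:
    """Fraction of women, per parity, whose later exams fall strictly below
    the partograph alert line (``start_dilatation`` + rate * elapsed hours,
    clocked from their first exam at or above ``start_dilatation``)."""
    crossed: dict[str, list[bool]] = {}
    for rec in records:
        qual = [(t, d) for t, d in rec.exams if d >= start_dilatation]
        if not qual:
            continue
        t0 = qual[0][0]
        hit = any(d < start_dilatation + rate_cm_per_h * (t - t0)
                  for t, d in rec.exams if t > t0)
        crossed.setdefault(rec.parity_group, []).append(hit)
    return {parity: float(np.mean(v)) for parity, v in crossed.items()}
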