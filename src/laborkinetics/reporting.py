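"""Orchestration: filters -> per-parity analyses -> tidy tables.

`run_full_analysis` runs the selection chain, then per parity group the
survival, Markov and logistic-curve analyses, optionally repeats survival and
Markov on the non-augmented subpopulation, and emits the difference-of-medians
sensitivity tables (all women minus women without oxytocin, signed).  Every
table is tidy CSV-ready with method/parity/population tags so the published
table layouts can be diffed mechanically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters, logistic, markov, survival
from .calibration import PARITY_GROUPS
from .cohort import LabourRecord, read_cohort  # noqa: F401  (re-exported)

log = logging.getLogger(__name__)

METHODS = ("survival", "markov", "logistic")


@dataclass
class AnalysisConfig:
    parities: tuple[str, ...] = PARITY_GROUPS
    methods: tuple[str, ...] = METHODS
    exclude_augmented: bool = False  # also run the sensitivity split
    seed: int = 0
    probs: tuple[float, ...] = (0.05, 0.5, 0.95)
    markov_step_h: float = markov.DEFAULT_STEP_H
    markov_nsim: int = 100_000
    min_stratum_n: int = 10

    def validate(self) -> None:
        bad = set(self.methods) - set(METHODS)
        if bad:
            raise ValueError(f"unknown methods: {sorted(bad)}")
        if not self.methods:
            raise ValueError("at least one method required")
        if any(not 0 < p < 1 for p in self.probs):
            raise ValueError("probs must lie in (0, 1)")


@dataclass
class ReportBundle:
    flow: filters.FlowCounts | None = None
    sojourn: dict[str, pd.DataFrame] = field(default_factory=dict)  # method -> table
    cumulative: dict[str, pd.DataFrame] = field(default_factory=dict)
    differences: dict[str, pd.DataFrame] = field(default_factory=dict)
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)  # per parity
    curve_params: dict[str, logistic.LogisticCurveParams] = field(default_factory=dict)
    intensities: dict[tuple[str, str], markov.IntensityMatrix] = field(default_factory=dict)
    alert_crossing: dict[str, float] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.flow is not None:
            (out / "flow_counts.json").write_text(self.flow.to_json())
            (out / "flow_chart.txt").write_text(self.flow.to_text() + "\n")
        for tag, df in {**self.sojourn, **self.cumulative, **self.differences}.items():
            df.round(2).to_csv(out / f"{tag}.csv", index=False)
        for parity, df in self.curves.items():
            df.round(4).to_csv(out / f"curve_parity_{parity.replace('+', 'plus')}.csv",
                               index=False)
        payload = dict(self.metadata)
        payload["alert_crossing"] = self.alert_crossing
        payload["curve_params"] = {
            p: {k: getattr(cp, k) for k in
                ("beta0", "beta1", "beta2", "sigma_b", "sigma_eps", "loglik")}
            for p, cp in self.curve_params.items()}
        payload["errors"] = self.errors
        (out / "run_metadata.json").write_text(json.dumps(payload, indent=2))


def admission_distribution(records: list[LabourRecord]) -> dict[int, float]:
    counts: dict[int, int] = {}
    for r in records:
        counts[r.admission_dilatation] = counts.get(r.admission_dilatation, 0) + 1
    total = sum(counts.values())
    return {d: c / total for d, c in counts.items()}


def _survival_tables(cohort_by_parity, cfg, tag):
    soj = [survival.sojourn_table(recs, parity_label=p, probs=cfg.probs,
                                  min_n=cfg.min_stratum_n)
           for p, recs in cohort_by_parity.items()]
    cum = [survival.cumulative_duration_table(recs, parity_label=p,
                                              probs=cfg.probs,
                                              min_n=cfg.min_stratum_n)
           for p, recs in cohort_by_parity.items()]
    return (pd.concat(soj, ignore_index=True).assign(method="survival", population=tag),
            pd.concat(cum, ignore_index=True).assign(method="survival", population=tag))


def _markov_tables(cohort_by_parity, cfg, tag, bundle):
    rng = np.random.default_rng(cfg.seed + 7)
    soj_parts, cum_parts = [], []
    for p, recs in cohort_by_parity.items():
        panels = markov.records_to_panels(recs)
        Q = markov.fit_intensities(panels)
        bundle.intensities[(tag, p)] = Q
        traj = markov.simulate_markov_cohort(
            Q, admission_distribution(recs), n=cfg.markov_nsim,
            step_h=cfg.markov_step_h, rng_seed=rng)
        soj_parts.append(markov.markov_sojourn_table(traj, parity_label=p,
                                                     probs=cfg.probs))
        cum_parts.append(markov.markov_cumulative_table(traj, parity_label=p,
                                                        probs=cfg.probs))
        if tag == "all":
            tau = np.arange(0.0, np.percentile(
                traj.entry_tick[:, -1][traj.reached(markov.N_TRANSIENT - 1)]
                * traj.step_h, 95), 0.25)
            bundle.curves[f"markov_{p}"] = markov.average_curve_markov(traj, tau)
    return (pd.concat(soj_parts, ignore_index=True).assign(method="markov", population=tag),
            pd.concat(cum_parts, ignore_index=True).assign(method="markov", population=tag))


def median_difference_table(all_women: pd.DataFrame,
                            non_augmented: pd.DataFrame) -> pd.DataFrame:
    """Signed difference of medians, all women minus women w/o oxytocin."""
    keys = [c for c in ("parity", "from_cm", "admission_cm", "to_cm")
            if c in all_women.columns]
    a = all_women.set_index(keys)["p50"]
    b = non_augmented.set_index(keys)["p50"]
    out = (a - b).rename("median_difference_h").reset_index()
    return out


def run_full_analysis(records: list[LabourRecord],
                      config: AnalysisConfig) -> ReportBundle:
    """Full pipeline on an assembled cohort; per-stratum failures are logged
    into the bundle and the remaining tables still emitted."""
    config.validate()
    bundle = ReportBundle(metadata={"seed": config.seed,
                                    "methods": list(config.methods)})
    t0 = time.perf_counter()
    included, flow = filters.apply_inclusion(records)
    bundle.flow = flow
    by_parity = {p: recs for (p,), recs in sorted(
        filters.stratify(included, ("parity_group",)).items())
        if p in config.parities}

    populations = {"all": by_parity}
    if config.exclude_augmented:
        populations["no_oxytocin"] = {
            p: filters.exclude_augmented(recs) for p, recs in by_parity.items()}

    for tag, cohort in populations.items():
        if "survival" in config.methods:
            try:
                soj, cum = _survival_tables(cohort, config, tag)
                bundle.sojourn[f"sojourn_survival_{tag}"] = soj
                bundle.cumulative[f"cumulative_survival_{tag}"] = cum
            except Exception as err:  # pragma: no cover - defensive
                bundle.errors.append(f"survival/{tag}: {err}")
                log.exception("survival stage failed for %s", tag)
        if "markov" in config.methods:
            try:
                soj, cum = _markov_tables(cohort, config, tag, bundle)
                bundle.sojourn[f"sojourn_markov_{tag}"] = soj
                bundle.cumulative[f"cumulative_markov_{tag}"] = cum
            except Exception as err:  # pragma: no cover - defensive
                bundle.errors.append(f"markov/{tag}: {err}")
                log.exception("markov stage failed for %s", tag)

    if "logistic" in config.methods:
        for p, recs in by_parity.items():
            try:
                obs = logistic.cohort_observations(recs)
                params = logistic.fit_logistic_nlmm(obs)
                bundle.curve_params[p] = params
                lo = float(obs["t_signed"].min())
                grid = np.linspace(lo, 0.0, 121)
                bundle.curves[f"logistic_{p}"] = logistic.average_curve_logistic(
                    params, grid, observed_range=(lo, 0.0))
            except Exception as err:
                bundle.errors.append(f"logistic/{p}: {err}")
                log.exception("logistic stage failed for parity %s", p)
        bundle.alert_crossing = logistic.alert_line_crossing(included)

    if config.exclude_augmented:
        for method in ("survival", "markov"):
            a = bundle.sojourn.get(f"sojourn_{method}_all")
            b = bundle.sojourn.get(f"sojourn_{method}_no_oxytocin")
            if a is not None and b is not None:
                bundle.differences[f"median_difference_{method}"] = (
                    median_difference_table(a, b))
    bundle.metadata["runtime_s"] = round(time.perf_counter() - t0, 2)
    log.info("analysis finished in %.1f s", bundle.metadata["runtime_s"])
    return bundle
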