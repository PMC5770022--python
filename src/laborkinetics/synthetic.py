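"""Synthetic labour cohorts with known ground truth.

Each woman's latent trajectory starts at 2 cm and advances one modelled level
at a time (2,3,...,8,10 cm) with independent log-normal sojourn times whose
(mu, sigma) are obtained by inverting the published per-parity median/95th
percentile pairs.  Admission happens at the instant the trajectory reaches the
admission dilatation (drawn from the published admission mix); sparse exams are
then observed on the admission clock at truncated-normal gaps until full
dilatation, whose time is recorded exactly.  The generator also plants records
violating each sample-selection criterion, with bookkeeping, so the filter
chain can be audited against known counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import calibration as cal
from .cohort import LabourRecord

#: modelled dilatation levels (no 9 cm state).
LEVELS = (2, 3, 4, 5, 6, 7, 8, 10)

#: selection criteria the generator can plant, in flow-chart order.
EXCLUSION_CRITERIA = (
    "not_term",
    "not_vertex",
    "induced_onset",
    "prior_uterine_scar",
    "intrapartum_cesarean",
    "adverse_outcome",
    "severe_malformation",
    "fewer_than_two_exams",
)

#: default planting rates (fraction of the included stratum size added as
#: excluded records); the source flow chart prints no usable counts, so these
#: are the generator's own realistic choices.
DEFAULT_EXCLUSION_RATES = {
    "not_term": 0.05,
    "not_vertex": 0.02,
    "induced_onset": 0.05,
    "prior_uterine_scar": 0.03,
    "intrapartum_cesarean": 0.06,
    "adverse_outcome": 0.02,
    "severe_malformation": 0.004,
    "fewer_than_two_exams": 0.03,
}


@dataclass
class GeneratorTruth:
    """Ground-truth parameters for one parity group."""

    parity_group: str
    sojourn_params: dict[tuple[int, int], tuple[float, float]]  # (mu, sigma) log-hours
    admission_mix: dict[int, float]  # over admission dilatations 2..6
    #: exam gaps are truncated normal; monitoring intensifies once the last
    #: observed dilatation reaches ``intensify_at_cm`` (advanced labour is
    #: examined far more often than the latent/early active phase).  The
    #: defaults are tuned so the per-woman exam count matches the published
    #: summary of 3 exams (10th pct 2) in every parity group.
    exam_gap_early_h: tuple[float, float, float] = (4.75, 1.5, 1.5)  # mean, SD, min
    exam_gap_late_h: tuple[float, float, float] = (1.0, 0.4, 0.3)
    intensify_at_cm: int = 7
    oxytocin_rate: float = 0.0
    exclusion_rates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.parity_group not in cal.PARITY_GROUPS:
            raise ValueError(f"unknown parity group {self.parity_group!r}")
        for tr, (mu, sigma) in self.sojourn_params.items():
            if sigma <= 0:
                raise ValueError(f"sigma must be > 0 for transition {tr}")
        mass = sum(self.admission_mix.values())
        if not np.isclose(mass, 1.0):
            raise ValueError(f"admission_mix sums to {mass}, not 1")
        if not 0.0 <= self.oxytocin_rate <= 1.0:
            raise ValueError("oxytocin_rate outside [0, 1]")
        for name, p in self.exclusion_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"exclusion rate {name} outside [0, 1]")


@dataclass
class TruePath:
    """Latent trajectory behind the observed exams (labour-onset clock)."""

    reaching_time: dict[int, float]  # level -> hours since reaching 2 cm
    admission_dilatation: int
    admission_time: float

    def level_at(self, t: float) -> int:
        """Integer dilatation occupied at onset-clock time ``t``."""
        level = LEVELS[0]
        for d in LEVELS:
            if self.reaching_time[d] <= t:
                level = d
            else:
                break
        return level


def default_truth(parity_group: str) -> GeneratorTruth:
    """Truth calibrated to the published percentile tables for one parity."""
    params: dict[tuple[int, int], tuple[float, float]] = {}
    table = cal.SURVIVAL_SOJOURN_PERCENTILES[parity_group]
    for tr in cal.TRANSITIONS:
        p50, _, p95 = table[tr]
        params[tr] = cal.lognormal_params_from_quantiles(p50, p95)
    params[(2, 3)] = params[(3, 4)]  # no published row below 3 cm
    truth = GeneratorTruth(
        parity_group=parity_group,
        sojourn_params=params,
        admission_mix=cal.admission_mix(parity_group),
        oxytocin_rate=cal.OXYTOCIN_RATE[parity_group],
        exclusion_rates=dict(DEFAULT_EXCLUSION_RATES),
    )
    truth.validate()
    return truth


def simulate_path(truth: GeneratorTruth, rng: np.random.Generator) -> TruePath:
    """Draw one latent trajectory: independent log-normal sojourns, cumulative
    reaching times, admission at the instant its dilatation is reached."""
    t = 0.0
    reaching = {LEVELS[0]: 0.0}
    for d, d_next in zip(LEVELS, LEVELS[1:]):
        mu, sigma = truth.sojourn_params[(d, d_next)]
        t += rng.lognormal(mean=mu, sigma=sigma)
        reaching[d_next] = t
    levels = np.array(sorted(truth.admission_mix))
    probs = np.array([truth.admission_mix[d] for d in levels])
    adm = int(rng.choice(levels, p=probs))
    return TruePath(reaching_time=reaching, admission_dilatation=adm, admission_time=reaching[adm])


def _gap(params: tuple[float, float, float], rng: np.random.Generator) -> float:
    # truncated normal via rejection; cap iterations for pathological configs
    mean, sd, mn = params
    for _ in range(100):
        g = rng.normal(mean, sd)
        if g >= mn:
            return g
    return mn


def observe_exams(path: TruePath, truth: GeneratorTruth, rng: np.random.Generator,
                  woman_id: str = "w0") -> LabourRecord:
    """Observe a latent path through sparse exams on the admission clock.

    The admission exam is at time 0; further exams follow at stochastic gaps,
    recording the integer level the path occupies, until full dilatation,
    which is appended as an exactly-timed final assessment (detecting 10 cm
    ends the first stage, so it counts as an assessment).
    """
    full_rel = path.reaching_time[10] - path.admission_time
    exams: list[tuple[float, int]] = [(0.0, path.admission_dilatation)]
    t_rel = 0.0
    while True:
        gap_params = (truth.exam_gap_late_h
                      if exams[-1][1] >= truth.intensify_at_cm
                      else truth.exam_gap_early_h)
        t_rel += _gap(gap_params, rng)
        if t_rel >= full_rel:
            break
        exams.append((t_rel, path.level_at(path.admission_time + t_rel)))
    exams.append((full_rel, 10))
    return LabourRecord(
        woman_id=woman_id,
        parity_group=truth.parity_group,
        exams=exams,
        gest_age_wk=_term_gest_age(rng),
        full_dilatation_time_h=full_rel,
        meta={"path": path},
    )


def _term_gest_age(rng: np.random.Generator) -> float:
    # cohort mean 38.74 (SD 1.11) weeks, truncated to the term window
    for _ in range(100):
        g = rng.normal(38.74, 1.11)
        if 37.0 <= g <= 41.0 + 6.0 / 7.0:
            return g
    return 39.0


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_per_parity: dict[str, int] = field(
        default_factory=lambda: dict(cal.STRATUM_N))
    oxytocin_rates: dict[str, float] = field(
        default_factory=lambda: dict(cal.OXYTOCIN_RATE))
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES))
    couple_augmentation: bool = False  # make augmented women the slow ones
    exam_gap_early_h: tuple[float, float, float] = (4.75, 1.5, 1.5)
    exam_gap_late_h: tuple[float, float, float] = (1.0, 0.4, 0.3)
    intensify_at_cm: int = 7

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_parity.values()):
            raise ValueError("cohort sizes must be >= 0")
        if sum(self.n_per_parity.values()) == 0 and not self.n_per_parity:
            raise ValueError("empty parity configuration")


def _plant_violation(rec: LabourRecord, criterion: str, rng: np.random.Generator) -> LabourRecord:
    rec = rec.copy()
    if criterion == "not_term":
        rec.gest_age_wk = float(rng.uniform(34.0, 36.85)) if rng.random() < 0.8 else float(rng.uniform(42.0, 43.0))
    elif criterion == "not_vertex":
        rec.presentation = "other"
    elif criterion == "induced_onset":
        rec.onset_type = "induced"
    elif criterion == "prior_uterine_scar":
        rec.prior_scar = True
    elif criterion == "intrapartum_cesarean":
        rec.mode_of_birth = "cesarean"
    elif criterion == "adverse_outcome":
        rec.adverse_outcome = True
    elif criterion == "severe_malformation":
        rec.severe_malformation = True
    elif criterion == "fewer_than_two_exams":
        rec.exams = rec.exams[:1]
    else:
        raise ValueError(f"unknown exclusion criterion {criterion!r}")
    rec.meta["planted_exclusion"] = criterion
    return rec


def _assign_oxytocin(records: list[LabourRecord], rate: float,
                     coupled: bool, rng: np.random.Generator) -> None:
    """Flag augmentation: independent Bernoulli by default, or coupled so
    that women with slow latent 3-5 cm progress are preferentially flagged
    (emulating selection of slow labours for augmentation)."""
    if not records:
        return
    if not coupled:
        flags = rng.random(len(records)) < rate
    else:
        slowness = np.array([
            _latent_slowness(r.meta["path"]) for r in records])
        median = np.median(slowness)
        p_slow = min(1.0, 1.5 * rate)
        # keep the marginal rate at `rate` given half the mass is slow
        p_fast = max(0.0, 2.0 * rate - p_slow)
        probs = np.where(slowness > median, p_slow, p_fast)
        flags = rng.random(len(records)) < probs
    for r, f in zip(records, flags):
        r.oxytocin = bool(f)


def _latent_slowness(path: TruePath) -> float:
    return (path.reaching_time[5] - path.reaching_time[3])


def generate_cohort(config: CohortConfig, seed: int,
                    ) -> tuple[list[LabourRecord], dict[str, dict[str, int]]]:
    """Generate a cohort plus per-parity planted-exclusion bookkeeping.

    Returns ``(records, planted)`` where ``planted[parity][criterion]`` counts
    the records constructed to violate exactly that selection criterion.  The
    configured ``n_per_parity`` records per stratum all pass the filter chain.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    records: list[LabourRecord] = []
    planted: dict[str, dict[str, int]] = {}
    counter = 0
    for parity in sorted(config.n_per_parity):
        n = config.n_per_parity[parity]
        truth = default_truth(parity)
        truth = replace(
            truth,
            exam_gap_early_h=config.exam_gap_early_h,
            exam_gap_late_h=config.exam_gap_late_h,
            intensify_at_cm=config.intensify_at_cm,
            oxytocin_rate=config.oxytocin_rates.get(parity, truth.oxytocin_rate),
            exclusion_rates=dict(config.exclusion_rates),
        )
        included: list[LabourRecord] = []
        for _ in range(n):
            path = simulate_path(truth, rng)
            rec = observe_exams(path, truth, rng, woman_id=f"w{counter:06d}")
            counter += 1
            included.append(rec)
        _assign_oxytocin(included, truth.oxytocin_rate,
                         config.couple_augmentation, rng)
        planted[parity] = {}
        extras: list[LabourRecord] = []
        for criterion in EXCLUSION_CRITERIA:
            p = truth.exclusion_rates.get(criterion, 0.0)
            n_extra = int(rng.binomial(n, p)) if n else 0
            planted[parity][criterion] = n_extra
            for _ in range(n_extra):
                path = simulate_path(truth, rng)
                rec = observe_exams(path, truth, rng, woman_id=f"w{counter:06d}")
                counter += 1
                rec.oxytocin = bool(rng.random() < truth.oxytocin_rate)
                extras.append(_plant_violation(rec, criterion, rng))
        records.extend(included)
        records.extend(extras)
    return records, planted
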