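"""Published percentile tables used to calibrate the synthetic cohort.

The values here are the printed per-parity sojourn percentiles (survival
column), admission-stratum sizes, oxytocin-augmentation rates and exam-count
summary of the source cohort study.  They are treated as *inputs*: the
synthetic generator inverts the log-normal quantile pairs (median, p95) to
per-transition (mu, sigma) so that downstream estimators can be validated
against known truth.
"""

from __future__ import annotations

import math

PARITY_GROUPS = ("0", "1", "2+")

#: transitions modelled between integer dilatation levels; 9 cm is never
#: documented, so 8 cm advances directly to full dilatation (10 cm).
TRANSITIONS = ((3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 10))

#: transitions simulated by the generator; the 2->3 cm step has no published
#: calibration row and reuses the 3->4 cm parameters.
GENERATOR_TRANSITIONS = ((2, 3),) + TRANSITIONS

#: survival-analysis sojourn percentiles, hours: {parity: {(d, d'): (p50, p5, p95)}}
SURVIVAL_SOJOURN_PERCENTILES = {
    "0": {
        (3, 4): (2.82, 0.60, 13.33),
        (4, 5): (1.72, 0.38, 7.83),
        (5, 6): (1.19, 0.23, 6.17),
        (6, 7): (0.66, 0.09, 4.92),
        (7, 8): (0.25, 0.02, 3.10),
        (8, 10): (0.87, 0.18, 4.19),
    },
    "1": {
        (3, 4): (2.42, 0.41, 14.18),
        (4, 5): (1.37, 0.25, 7.65),
        (5, 6): (0.79, 0.13, 4.95),
        (6, 7): (0.33, 0.03, 3.67),
        (7, 8): (0.09, 0.00, 2.69),
        (8, 10): (0.64, 0.11, 3.56),
    },
    "2+": {
        (3, 4): (2.35, 0.31, 17.85),
        (4, 5): (1.18, 0.17, 8.05),
        (5, 6): (0.79, 0.10, 6.24),
        (6, 7): (0.31, 0.03, 3.29),
        (7, 8): (0.17, 0.01, 2.44),
        (8, 10): (0.68, 0.12, 3.77),
    },
}

#: Markov-model sojourn percentiles, hours (same layout); kept for reference
#: and for cross-model sanity bands in tests.
MARKOV_SOJOURN_PERCENTILES = {
    "0": {
        (3, 4): (1.83, 0.08, 8.17),
        (4, 5): (1.58, 0.08, 7.08),
        (5, 6): (0.83, 0.00, 3.83),
        (6, 7): (0.92, 0.00, 4.25),
        (7, 8): (0.58, 0.00, 2.50),
        (8, 10): (0.75, 0.00, 3.33),
    },
    "1": {
        (3, 4): (1.92, 0.08, 8.33),
        (4, 5): (1.42, 0.08, 6.42),
        (5, 6): (0.83, 0.00, 3.58),
        (6, 7): (0.75, 0.00, 3.50),
        (7, 8): (0.42, 0.00, 1.83),
        (8, 10): (0.67, 0.00, 2.92),
    },
    "2+": {
        (3, 4): (2.17, 0.08, 9.75),
        (4, 5): (1.50, 0.08, 6.50),
        (5, 6): (0.75, 0.00, 3.33),
        (6, 7): (0.83, 0.00, 3.58),
        (7, 8): (0.33, 0.00, 1.50),
        (8, 10): (0.50, 0.00, 2.50),
    },
}

#: women per parity stratum in the analysed sample.
STRATUM_N = {"0": 2166, "1": 1488, "2+": 1952}

#: women per (parity, admission dilatation) cell of the cumulative-duration
#: analysis; admissions below 3 cm are not tabulated and make up the rest.
ADMISSION_N = {
    "0": {3: 249, 4: 715, 5: 316, 6: 322},
    "1": {3: 164, 4: 491, 5: 292, 6: 320},
    "2+": {3: 231, 4: 626, 5: 385, 6: 414},
}

#: fraction of labours augmented with oxytocin, by parity.
OXYTOCIN_RATE = {"0": 0.400, "1": 0.298, "2+": 0.267}

#: first-stage vaginal-exam count per woman: median (10th, 90th percentiles).
EXAM_COUNT_SUMMARY = (3, 2, 5)

#: retained after excluding augmented labours (sensitivity analysis), by parity.
NON_AUGMENTED_N = {"0": 1300, "1": 1044, "2+": 1430}

_Z95 = 1.6448536269514722  # standard normal 95th-percentile deviate


def lognormal_params_from_quantiles(median: float, p95: float) -> tuple[float, float]:
    """Invert (median, 95th percentile) of a log-normal to (mu, sigma).

    median = exp(mu) and p95 = exp(mu + 1.645 sigma), so
    mu = ln median, sigma = (ln p95 - ln median) / 1.645.
    """
    if median <= 0 or p95 <= median:
        raise ValueError("need 0 < median < p95 to identify a log-normal")
    mu = math.log(median)
    sigma = (math.log(p95) - mu) / _Z95
    return mu, sigma


def admission_mix(parity_group: str) -> dict[int, float]:
    """Admission-dilatation distribution over {2..6} cm for one parity group.

    The tabulated cells give the 3-6 cm mass; the remainder of the stratum
    (women arriving before 3 cm) is pooled at 2 cm, consistent with the
    reported 10th percentile of admission dilatation being 2 cm.
    """
    counts = dict(ADMISSION_N[parity_group])
    total = STRATUM_N[parity_group]
    counts[2] = total - sum(counts.values())
    return {d: counts[d] / total for d in sorted(counts)}
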