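import numpy as np
import pytest

from laborkinetics.synthetic import (
    CohortConfig,
    default_truth,
    generate_cohort,
    observe_exams,
    simulate_path,
)


@pytest.fixture(scope="session")
def parity0_truth():
    return default_truth("0")


@pytest.fixture(scope="session")
def small_cohort():
    """A mixed-parity cohort with planted exclusions (seeded, session-wide)."""
    cfg = CohortConfig(n_per_parity={"0": 150, "1": 100, "2+": 120})
    return generate_cohort(cfg, seed=42)


@pytest.fixture(scope="session")
def parity0_cohort():
    """A clean parity-0 cohort (no planted exclusions) of 800 women."""
    cfg = CohortConfig(n_per_parity={"0": 800}, exclusion_rates={})
    records, _ = generate_cohort(cfg, seed=7)
    return records


@pytest.fixture(scope="session")
def dense_exam_cohort():
    """Parity-0 cohort examined hourly: interval censoring fine enough that
    every sojourn distribution is well identified."""
    cfg = CohortConfig(
        n_per_parity={"0": 1200}, exclusion_rates={},
        exam_gap_early_h=(1.0, 0.3, 0.4), exam_gap_late_h=(0.8, 0.25, 0.3))
    records, _ = generate_cohort(cfg, seed=13)
    return records


@pytest.fixture()
def single_path(parity0_truth):
    rng = np.random.default_rng(3)
    return simulate_path(parity0_truth, rng)


@pytest.fixture()
def single_record(parity0_truth, single_path):
    rng = np.random.default_rng(4)
    return observe_exams(single_path, parity0_truth, rng, woman_id="w0")
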