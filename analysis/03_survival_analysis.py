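"""Interval-censored log-normal survival analysis of the included cohort.

Per parity group: sojourn-time percentile tables (3-4 cm ... 8-10 cm),
cumulative-duration tables by admission dilatation, and the 95th-percentile
staircase thresholds for protracted labour. All times in decimal hours.

Run:  python analysis/03_survival_analysis.py
"""

from pathlib import Path

import pandas as pd

from laborkinetics.cohort import read_cohort
from laborkinetics.filters import stratify
from laborkinetics.survival import (
    cumulative_duration_table,
    sojourn_table,
    staircase_series,
)

OUT = Path("results")


def main() -> None:
    included = read_cohort(OUT / "cohort_included.csv")
    groups = dict(sorted(stratify(included, ("parity_group",)).items()))

    soj = pd.concat([sojourn_table(recs, parity_label=p)
                     for (p,), recs in groups.items()], ignore_index=True)
    cum = pd.concat([cumulative_duration_table(recs, parity_label=p)
                     for (p,), recs in groups.items()], ignore_index=True)
    soj.round(2).to_csv(OUT / "sojourn_survival.csv", index=False)
    cum.round(2).to_csv(OUT / "cumulative_survival.csv", index=False)

    stair_rows = []
    for (p,), _ in groups.items():
        sub = cum[cum.parity == p]
        for adm in (3, 4, 5, 6):
            for level, hours in staircase_series(sub, adm, prob=0.95):
                stair_rows.append((p, adm, level, round(hours, 2)))
    pd.DataFrame(stair_rows, columns=["parity", "admission_cm", "to_cm",
                                      "p95_h"]).to_csv(
        OUT / "staircase_p95_survival.csv", index=False)

    print("sojourn percentiles (median (p5, p95) hours):")
    print(soj.round(2).to_string(index=False))
    print("\ncumulative duration to full dilatation:")
    print(cum[cum.to_cm == 10].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
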