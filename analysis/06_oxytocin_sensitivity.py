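"""Sensitivity analysis: all women versus labours without oxytocin.

Re-runs the survival and Markov sojourn/cumulative tables on the cohort
with augmented labours excluded and writes the signed difference-of-medians
tables (all women minus women without oxytocin).

Run:  python analysis/06_oxytocin_sensitivity.py [--seed 11] [--nsim 50000]
"""

import argparse
from pathlib import Path

from laborkinetics.cohort import read_cohort
from laborkinetics.reporting import AnalysisConfig, run_full_analysis

OUT = Path("results")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--nsim", type=int, default=50_000)
    args = ap.parse_args()

    records = read_cohort(OUT / "cohort.csv")
    cfg = AnalysisConfig(methods=("survival", "markov"), seed=args.seed,
                         exclude_augmented=True, markov_nsim=args.nsim)
    bundle = run_full_analysis(records, cfg)
    for name, df in bundle.differences.items():
        df.round(2).to_csv(OUT / f"{name}.csv", index=False)
        print(f"== {name}")
        print(df.round(2).to_string(index=False))
    for tag in ("sojourn_survival_no_oxytocin", "sojourn_markov_no_oxytocin"):
        bundle.sojourn[tag].round(2).to_csv(OUT / f"{tag}.csv", index=False)


if __name__ == "__main__":
    main()
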