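"""Apply the sample-selection chain and report the funnel.

Reads results/cohort.csv, excludes non-term, non-vertex, induced,
high-admission, scarred, caesarean, adverse-outcome, malformation and
single-exam records (attributed to the first failing criterion), and writes
the included cohort plus the flow counts.

Run:  python analysis/02_select_sample.py
"""

from pathlib import Path

from laborkinetics.cohort import read_cohort, write_cohort
from laborkinetics.filters import apply_inclusion, stratify

OUT = Path("results")


def main() -> None:
    records = read_cohort(OUT / "cohort.csv")
    included, flow = apply_inclusion(records)
    write_cohort(included, OUT / "cohort_included.csv")
    (OUT / "flow_counts.json").write_text(flow.to_json())
    print(flow.to_text())
    sizes = {p: len(v) for (p,), v in
             sorted(stratify(included, ("parity_group",)).items())}
    print("parity strata:", sizes)
    oxy = {p: round(100 * sum(r.oxytocin for r in v) / len(v), 1)
           for (p,), v in sorted(stratify(included, ("parity_group",)).items())}
    print("oxytocin %:", oxy)


if __name__ == "__main__":
    main()
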