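"""Average labour curves from the logistic growth mixed model.

Anchors every woman's exams at full dilatation (reverse time), fits the
three-parameter logistic mixed model per parity, writes the population
curves over the observed range, and computes the fraction of women crossing
the 1 cm/hour partograph alert line.

Run:  python analysis/05_labour_curves.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from laborkinetics.cohort import read_cohort
from laborkinetics.filters import stratify
from laborkinetics.logistic import (
    alert_line_crossing,
    average_curve_logistic,
    cohort_observations,
    fit_logistic_nlmm,
)

OUT = Path("results")


def main() -> None:
    included = read_cohort(OUT / "cohort_included.csv")
    params_out, curves = {}, []
    for (p,), recs in sorted(stratify(included, ("parity_group",)).items()):
        obs = cohort_observations(recs)
        fit = fit_logistic_nlmm(obs)
        lo = float(obs.t_signed.min())
        curve = average_curve_logistic(fit, np.linspace(lo, 0.0, 121),
                                       observed_range=(lo, 0.0))
        curves.append(curve.assign(parity=p))
        params_out[p] = {
            "beta0": fit.beta0, "beta1": fit.beta1, "beta2": fit.beta2,
            "sigma_b": fit.sigma_b, "sigma_eps": fit.sigma_eps,
            "loglik": fit.loglik, "se": fit.se, "n_women": fit.n_women,
            "inflection_outside_observed_range":
                bool(curve.attrs["inflection_outside_observed_range"]),
        }
        print(f"parity {p}: curve 4 h / 1 h before full dilatation = "
              f"{np.interp(-4.0, curve.t_signed, curve.dilatation):.2f} / "
              f"{np.interp(-1.0, curve.t_signed, curve.dilatation):.2f} cm"
              f" (inflection outside range: "
              f"{params_out[p]['inflection_outside_observed_range']})")

    pd.concat(curves, ignore_index=True).round(4).to_csv(
        OUT / "average_curve_logistic.csv", index=False)
    (OUT / "logistic_params.json").write_text(json.dumps(params_out, indent=2))

    crossing = alert_line_crossing(included)
    (OUT / "alert_line_crossing.json").write_text(json.dumps(crossing, indent=2))
    print("alert-line crossing fractions:",
          {k: round(v, 3) for k, v in crossing.items()})


if __name__ == "__main__":
    main()
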