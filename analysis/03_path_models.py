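"""Fit and compare the two path models on the simulated cohort.

Model 1 includes the acute ischemic lesion volume (WML -> ILV -> cognition);
Model 2 drops it. Both are fitted by maximum likelihood to the sample
covariance of the cohort written by 01_simulate_cohort.py, and compared on
chi2, CFI, GFI, AGFI and RMSEA. Writes results/path_models.json.
"""

import json
from pathlib import Path

import pandas as pd

import strokesem as sk
from strokesem.sem import model_with_ilv, model_without_ilv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort_simulated.csv", index_col="subject")
    fits = {}
    for name, spec in (("model_1", model_with_ilv()), ("model_2", model_without_ilv())):
        S = cohort[list(spec.variables)].cov()
        fits[name] = sk.fit_ml(spec, S, n=len(cohort))
        print(f"{name}:")
        print(fits[name].summary())
    report = sk.compare_models(fits["model_1"], fits["model_2"])
    print(f"preferred model: {report['preferred']}")
    payload = {
        name: {
            "indices": fits[name].indices,
            "std_coefficients": {f"{a}->{b}": v for (a, b), v in fits[name].std_coefficients.items()},
            "converged": fits[name].converged,
        }
        for name in fits
    }
    payload["comparison"] = report
    (RESULTS / "path_models.json").write_text(json.dumps(payload, indent=2, default=float))
    print(f"wrote {RESULTS / 'path_models.json'}")


if __name__ == "__main__":
    main()
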