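"""Supporting statistics on the simulated cohort.

Correlation matrix with the strict p < 0.005 flag, unadjusted-then-multiple
regression for the cognitive outcome, one-way ANOVA by infarct location and
the lesion-presence t-test with WML-adjusted ANCOVA. Writes results/stats/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import strokesem as sk

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 2) -> None:
    cohort = pd.read_csv(RESULTS / "cohort_simulated.csv", index_col="subject")
    out = RESULTS / "stats"
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # attach group structure: lesion presence follows the simulated ILV
    cohort["has_infarct"] = cohort["ilv"] > cohort["ilv"].quantile(50 / 142)
    locs = np.array(["cortical", "subcortical", "subtentorial"])
    cohort["infarct_location"] = np.where(
        cohort["has_infarct"], rng.choice(locs, size=len(cohort), p=[0.33, 0.52, 0.15]), "none"
    )
    cohort["wml_volume_mm3_log10"] = cohort["wml"]  # already on a log-like scale

    corr = sk.correlation_battery(
        cohort,
        rows=("cognition",),
        cols=("age", "education", "wml", "nawm_integrity", "ilv"),
    )
    corr["r"].round(3).to_csv(out / "correlations_r.csv")
    flagged = corr["significant"].loc["cognition"]
    print("correlations with cognition (flag = p<0.005):")
    for col in corr["r"].columns:
        print(f"  {col:15s} r={corr['r'].loc['cognition', col]:+.3f} "
              f"{'*' if flagged[col] else ''}")

    reg = sk.regression_battery(
        cohort, "cognition", ("age", "education", "wml", "nawm_integrity", "ilv")
    )
    reg["unadjusted"].round(4).to_csv(out / "regression_unadjusted.csv")
    if reg["adjusted"] is not None:
        reg["adjusted"].round(4).to_csv(out / "regression_adjusted.csv")
    print(f"adjusted model: predictors {reg['selected']}, R^2 = {reg['r2']:.3f}")

    anova = sk.location_anova(cohort)
    print(
        f"ANOVA by location: F({anova['df'][0]},{anova['df'][1]}) = "
        f"{anova['F']:.2f}, p = {anova['p']:.3f}"
    )

    anc = sk.lesion_presence_ancova(cohort)
    print(
        f"presence t({anc['t_df']}) = {anc['t']:.2f} (p = {anc['t_p']:.3f}); "
        f"WML-adjusted F = {anc['ancova_F']:.2f} (p = {anc['ancova_p']:.3f})"
    )
    (out / "group_tests.json").write_text(
        json.dumps({"anova": {k: anova[k] for k in ("F", "df", "p")}, "ancova": anc},
                   indent=2, default=float)
    )
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
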