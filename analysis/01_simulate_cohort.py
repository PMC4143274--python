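"""Simulate the tabular study cohort (n = 142).

Draws a cohort from the recursive path model in which age drives white-matter
lesion (WML) burden and (inverse) white-matter integrity, both of which
together with education drive the one-year global cognitive score, while the
acute ischemic lesion volume (ILV) is related to age and education but has no
direct effect on cognition. Lesion volumes are skew-transformed and rescaled
to realistic units. Writes results/cohort_simulated.csv.
"""

from pathlib import Path

import strokesem as sk

OUT = Path(__file__).resolve().parents[1] / "results"

PATHS = {
    ("education", "cognition"): 0.328,
    ("age", "wml"): 0.306,
    ("age", "nawm_integrity"): 0.370,
    ("wml", "cognition"): -0.231,
    ("nawm_integrity", "cognition"): -0.176,
    ("age", "ilv"): 0.30,
    ("education", "ilv"): -0.30,
}


def main(seed: int = 1) -> None:
    spec = sk.CohortModelSpec(
        n_subjects=142,
        variables=("age", "education", "wml", "nawm_integrity", "ilv", "cognition"),
        path_coefficients=PATHS,
        exogenous_correlations={("age", "education"): -0.10},
        skew_transform=("wml", "ilv"),
        variable_scales={
            "age": (65.9, 9.5),
            "education": (13.6, 3.7),
            "cognition": (96.7, 12.4),
        },
        seed=seed,
    )
    cohort = sk.simulate_cohort(spec)
    OUT.mkdir(exist_ok=True)
    cohort.to_csv(OUT / "cohort_simulated.csv", index_label="subject")

    corr = cohort.corr()
    print(f"simulated cohort: n = {len(cohort)}")
    print(f"  corr(age, wml)            = {corr.loc['age', 'wml']:+.3f}")
    print(f"  corr(education, cognition)= {corr.loc['education', 'cognition']:+.3f}")
    print(f"  corr(wml, cognition)      = {corr.loc['wml', 'cognition']:+.3f}")
    print(f"  corr(ilv, cognition)      = {corr.loc['ilv', 'cognition']:+.3f}")
    print(f"wrote {OUT / 'cohort_simulated.csv'}")


if __name__ == "__main__":
    main()
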