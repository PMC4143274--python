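"""Cohort-level statistical battery.

Covers the supporting analyses around the path models: log transformation of
skewed lesion volumes, Pearson/Spearman correlation matrices with a strict
significance threshold, unadjusted-then-multiple linear regression with
standardized coefficients, one-way ANOVA of cognition by infarct location,
and the lesion-presence t-test with a WML-volume-adjusted ANCOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as smapi
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

__all__ = [
    "log_transform_volumes",
    "correlation_battery",
    "regression_battery",
    "location_anova",
    "lesion_presence_ancova",
    "two_sample_t_from_summary",
]

LOCATION_LEVELS = ("none", "cortical", "subcortical", "subtentorial")


def log_transform_volumes(
    cohort: pd.DataFrame,
    columns: tuple[str, ...] = ("wml_volume_mm3", "ischemic_volume_mm3"),
    epsilon: float = 8.0,
    suffix: str = "_log10",
) -> pd.DataFrame:
    """log10(volume + epsilon) for skewed volume columns.

    ``epsilon`` (default one 2x2x2 mm voxel) keeps zero volumes finite — a
    subject can have no visible infarct — while preserving rank order.
    """
    out = cohort.copy()
    for col in columns:
        v = out[col].to_numpy(dtype=float)
        if np.any(v < 0):
            raise ValueError(f"negative volumes in {col!r}")
        out[col + suffix] = np.log10(v + epsilon)
    return out


def correlation_battery(
    cohort: pd.DataFrame,
    rows: tuple[str, ...],
    cols: tuple[str, ...],
    ordinal: frozenset[str] | set[str] = frozenset(),
    alpha: float = 0.005,
) -> dict[str, pd.DataFrame]:
    """Pairwise correlations (Pearson; Spearman when either variable is
    declared ordinal) with significance flags at a strict ``alpha``."""
    r = pd.DataFrame(index=list(rows), columns=list(cols), dtype=float)
    p = r.copy()
    for a in rows:
        for b in cols:
            pair = cohort[[a, b]].dropna()
            if len(pair) < 4 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                continue  # leave NaN: degenerate cell
            if a in ordinal or b in ordinal:
                rr, pp = sps.spearmanr(pair[a], pair[b])
            else:
                rr, pp = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b], p.loc[a, b] = rr, pp
    return {"r": r, "p": p, "significant": p < alpha}


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def regression_battery(
    cohort: pd.DataFrame,
    outcome: str,
    predictors: tuple[str, ...],
    entry_alpha: float = 0.05,
) -> dict:
    """Unadjusted standardized regressions per predictor, then one multiple
    regression on the predictors significant at ``entry_alpha``."""
    rows = []
    for pred in predictors:
        sub = cohort[[outcome, pred]].dropna()
        if len(sub) < 10:
            raise ValueError(f"fewer than 10 complete cases for predictor {pred!r}")
        y = _zscore(sub[outcome].to_numpy(dtype=float))
        x = _zscore(sub[pred].to_numpy(dtype=float))
        fit = smapi.OLS(y, smapi.add_constant(x)).fit()
        rows.append(
            {
                "predictor": pred,
                "beta_std": fit.params[1],
                "se": fit.bse[1],
                "p": fit.pvalues[1],
                "n": len(sub),
            }
        )
    unadjusted = pd.DataFrame(rows).set_index("predictor")

    selected = list(unadjusted.index[unadjusted["p"] < entry_alpha])
    adjusted = None
    r2 = np.nan
    if selected:
        sub = cohort[[outcome] + selected].dropna()
        Z = np.column_stack([_zscore(sub[c].to_numpy(dtype=float)) for c in selected])
        if np.linalg.cond(Z.T @ Z) > 1e8:
            raise ValueError("selected predictors are collinear (condition number > 1e8)")
        y = _zscore(sub[outcome].to_numpy(dtype=float))
        fit = smapi.OLS(y, smapi.add_constant(Z)).fit()
        adjusted = pd.DataFrame(
            {
                "beta_std": fit.params[1:],
                "se": fit.bse[1:],
                "p": fit.pvalues[1:],
            },
            index=selected,
        )
        r2 = float(fit.rsquared)
    return {"unadjusted": unadjusted, "selected": selected, "adjusted": adjusted, "r2": r2}


def location_anova(
    cohort: pd.DataFrame,
    group_col: str = "infarct_location",
    value_col: str = "cognition",
) -> dict:
    """One-way ANOVA of the outcome across infarct-location groups."""
    groups, means = [], {}
    for level, sub in cohort.groupby(group_col, observed=True):
        vals = sub[value_col].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"group {level!r} has fewer than 2 observations; dropped")
            continue
        groups.append(vals)
        means[level] = {"n": len(vals), "mean": vals.mean(), "sd": vals.std(ddof=1)}
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups for ANOVA")
    F, p = sps.f_oneway(*groups)
    df_between = len(groups) - 1
    df_within = sum(len(g) for g in groups) - len(groups)
    return {
        "F": float(F),
        "df": (df_between, df_within),
        "p": float(p),
        "group_summary": pd.DataFrame(means).T,
    }


def lesion_presence_ancova(
    cohort: pd.DataFrame,
    outcome: str = "cognition",
    presence_col: str = "has_infarct",
    covariate: str = "wml_volume_mm3_log10",
) -> dict:
    """Two-sample t-test for lesion presence, then ANCOVA adjusting for WML
    volume (Type-II F for the group term)."""
    sub = cohort[[outcome, presence_col, covariate]].dropna().copy()
    g1 = sub.loc[sub[presence_col].astype(bool), outcome].to_numpy(dtype=float)
    g0 = sub.loc[~sub[presence_col].astype(bool), outcome].to_numpy(dtype=float)
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both presence groups must be non-empty")
    if sub[covariate].nunique() < 2:
        raise ValueError("covariate is constant; ANCOVA undefined")
    t, t_p = sps.ttest_ind(g1, g0, equal_var=True)
    sub["_grp"] = sub[presence_col].astype(bool).astype(int)
    model = smf.ols(f"{outcome} ~ C(_grp) + {covariate}", data=sub).fit()
    tab = anova_lm(model, typ=2)
    return {
        "t": float(t),
        "t_df": len(g0) + len(g1) - 2,
        "t_p": float(t_p),
        "ancova_F": float(tab.loc["C(_grp)", "F"]),
        "ancova_p": float(tab.loc["C(_grp)", "PR(>F)"]),
        "group_means": {"with_lesion": float(g1.mean()), "without_lesion": float(g0.mean())},
    }


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-SD two-sample t statistic and df from printed group summaries."""
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    t = (mean2 - mean1) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), n1 + n2 - 2
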