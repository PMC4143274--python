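"""Simulated cohort tables drawn from a user-specified recursive path model.

Variables are generated in topological order: exogenous variables come from a
unit-variance multivariate normal with the requested correlations; each
endogenous variable is the stated linear combination of its parents plus
independent Gaussian noise. With standardized path weights and auto-computed
residual SDs every variable has unit variance before optional rescaling, so
the stated weights are the model-implied standardized coefficients. Selected
variables can be exponentiated (then rescaled back to a target mean/SD) to
mimic the right-skewed distribution of lesion volumes.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortModelSpec", "simulate_cohort", "implied_correlation"]


@dataclass(frozen=True)
class CohortModelSpec:
    n_subjects: int
    variables: tuple[str, ...]
    path_coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    exogenous_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    residual_sds: dict[str, float] | None = None  # None: standardize to unit variance
    skew_transform: tuple[str, ...] = ()
    # optional final affine rescale: name -> (mean, sd)
    variable_scales: dict[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        names = set(self.variables)
        for (a, b), w in self.path_coefficients.items():
            if a not in names or b not in names:
                raise ValueError(f"edge ({a}, {b}) references unknown variable")
            if not (-1.0 < w < 1.0):
                raise ValueError(f"standardized weight for ({a}, {b}) must lie in (-1, 1)")
        for a, b in self.exogenous_correlations:
            if a not in names or b not in names:
                raise ValueError(f"correlation pair ({a}, {b}) references unknown variable")
        self.topological_order()  # raises on cycles

    def parents(self, var: str) -> list[tuple[str, float]]:
        return [(a, w) for (a, b), w in self.path_coefficients.items() if b == var]

    def endogenous(self) -> set[str]:
        return {b for (_a, b) in self.path_coefficients}

    def topological_order(self) -> list[str]:
        ts = graphlib.TopologicalSorter({v: [] for v in self.variables})
        for a, b in self.path_coefficients:
            ts.add(b, a)
        try:
            order = list(ts.static_order())
        except graphlib.CycleError as err:
            raise ValueError("path diagram contains a cycle") from err
        return order


def implied_correlation(spec: CohortModelSpec) -> pd.DataFrame:
    """Model-implied correlation matrix (before skew/rescale transforms).

    Built recursively: cov(y, z) = sum_p beta_p cov(p, z) for each endogenous
    y with parents p, residuals independent of everything upstream.
    """
    order = spec.topological_order()
    endo = spec.endogenous()
    exo = [v for v in spec.variables if v not in endo]
    idx = {v: i for i, v in enumerate(spec.variables)}
    C = np.eye(len(spec.variables))
    for (a, b), r in spec.exogenous_correlations.items():
        if a in endo or b in endo:
            raise ValueError(f"correlation ({a}, {b}) involves an endogenous variable")
        C[idx[a], idx[b]] = C[idx[b], idx[a]] = r
    for v in order:
        if v not in endo:
            continue
        pars = spec.parents(v)
        for z in spec.variables:
            if z == v:
                continue
            cov = sum(w * C[idx[p], idx[z]] for p, w in pars)
            C[idx[v], idx[z]] = C[idx[z], idx[v]] = cov
        explained = sum(
            wa * wb * C[idx[pa], idx[pb]] for pa, wa in pars for pb, wb in pars
        )
        if spec.residual_sds is None:
            if explained >= 1.0:
                raise ValueError(f"weights into {v!r} explain >= 100% variance; not standardizable")
            C[idx[v], idx[v]] = 1.0
        else:
            C[idx[v], idx[v]] = explained + spec.residual_sds[v] ** 2
    out = pd.DataFrame(C, index=list(spec.variables), columns=list(spec.variables))
    # scale to correlation if residual_sds produced non-unit variances
    d = np.sqrt(np.diag(C))
    out.loc[:, :] = C / np.outer(d, d)
    eigvals = np.linalg.eigvalsh(out.to_numpy())
    if eigvals.min() <= -1e-10:
        raise ValueError("implied correlation matrix is not positive semidefinite")
    return out


def _residual_sd(spec: CohortModelSpec, var: str, C: pd.DataFrame) -> float:
    if spec.residual_sds is not None:
        return float(spec.residual_sds[var])
    pars = spec.parents(var)
    explained = sum(
        wa * wb * C.loc[pa, pb] for pa, wa in pars for pb, wb in pars
    )
    return float(np.sqrt(max(1.0 - explained, 0.0)))


def simulate_cohort(spec: CohortModelSpec) -> pd.DataFrame:
    """Draw ``n_subjects`` rows from the path model. Pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    order = spec.topological_order()
    endo = spec.endogenous()
    exo = [v for v in spec.variables if v not in endo]

    # correlation matrix restricted to exogenous variables (unit variances)
    ce = np.eye(len(exo))
    pos = {v: i for i, v in enumerate(exo)}
    for (a, b), r in spec.exogenous_correlations.items():
        ce[pos[a], pos[b]] = ce[pos[b], pos[a]] = r
    if np.linalg.eigvalsh(ce).min() <= 0:
        raise ValueError("exogenous correlation matrix is not positive definite")
    exo_draws = rng.multivariate_normal(np.zeros(len(exo)), ce, size=spec.n_subjects,
                                        method="cholesky")

    # residual SDs need the implied covariance among parents
    C = implied_correlation(spec) if spec.residual_sds is None else None
    data: dict[str, np.ndarray] = {}
    for v in order:
        if v in endo:
            pars = spec.parents(v)
            sd = _residual_sd(spec, v, C) if C is not None else float(spec.residual_sds[v])
            data[v] = sum(w * data[p] for p, w in pars) + sd * rng.normal(
                size=spec.n_subjects
            )
        else:
            data[v] = exo_draws[:, pos[v]]

    df = pd.DataFrame({v: data[v] for v in spec.variables})
    for v in spec.skew_transform:
        x = df[v].to_numpy()
        m, s = x.mean(), x.std(ddof=1)
        y = np.exp(x)  # monotone, right-skews the distribution
        y = (y - y.mean()) / y.std(ddof=1) * s + m
        df[v] = y
    for v, (mean, sd) in spec.variable_scales.items():
        x = df[v].to_numpy()
        df[v] = (x - x.mean()) / x.std(ddof=1) * sd + mean
    return df
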