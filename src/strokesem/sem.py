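"""Recursive path analysis (observed-variable SEM) by maximum likelihood.

Model: y = B y + e with a strictly lower-triangularizable (acyclic) path
coefficient matrix B and covariance matrix Psi for exogenous variables and
residuals. The model-implied covariance is

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T.

Free parameters are the path coefficients (one per directed edge), every
variance (parameterized on the log scale to enforce positivity) and any
explicitly freed covariances. Fitting minimizes the Wishart ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,

with the analytic gradient, quasi-Newton multistarts from a deterministic
closed-form initialization, and a Newton polish on the gradient. The test
statistic is chi2 = (n - 1) F_ML with df = p(p+1)/2 minus the number of free
parameters. Fit indices follow the conventional definitions:

    CFI   = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)
    GFI   = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]
    AGFI  = 1 - [p(p+1) / (2 df)] (1 - GFI)
    RMSEA = sqrt(max(chi2 - df, 0) / (df (n - 1)))

with the independence model (all covariances zero, variances free) as the
CFI baseline. Standardized coefficients rescale raw ones by the ratio of
model-implied SDs at the solution.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModelSpec",
    "PathModelFit",
    "implied_covariance",
    "fit_ml",
    "fit_indices",
    "baseline_chi2",
    "compare_models",
    "model_with_ilv",
    "model_without_ilv",
    "parse_model_text",
    "model_from_yaml",
    "FIT_CRITERIA",
]

# conventional good-fit thresholds used for model comparison
FIT_CRITERIA = {"p_value": 0.05, "cfi": 0.95, "gfi": 0.95, "agfi": 0.95, "rmsea": 0.08}

Edge = tuple[str, str]


@dataclass(frozen=True)
class PathModelSpec:
    """Variables, directed paths and freed covariances of a recursive model."""

    variables: tuple[str, ...]
    edges: tuple[Edge, ...]
    exogenous_covariances: tuple[Edge, ...] = ()
    residual_covariances: tuple[Edge, ...] = ()

    def __post_init__(self) -> None:
        names = set(self.variables)
        if len(names) != len(self.variables):
            raise ValueError("duplicate variable names")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges")
        for a, b in self.edges + self.exogenous_covariances + self.residual_covariances:
            if a not in names or b not in names:
                raise ValueError(f"({a}, {b}) references an unknown variable")
        endo = {b for _, b in self.edges}
        for a, b in self.exogenous_covariances:
            if a in endo or b in endo:
                raise ValueError(f"exogenous covariance ({a}, {b}) touches an endogenous variable")
        ts = graphlib.TopologicalSorter({v: [] for v in self.variables})
        for a, b in self.edges:
            ts.add(b, a)
        try:
            list(ts.static_order())
        except graphlib.CycleError as err:
            raise ValueError("path diagram contains a cycle") from err

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def covariance_pairs(self) -> tuple[Edge, ...]:
        return self.exogenous_covariances + self.residual_covariances

    @property
    def n_free_parameters(self) -> int:
        return len(self.edges) + self.p + len(self.covariance_pairs)

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free_parameters

    def index(self, name: str) -> int:
        return self.variables.index(name)


# ---------------------------------------------------------------------------
# implied covariance


def _matrices(spec: PathModelSpec, betas: np.ndarray, variances: np.ndarray,
              covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = spec.p
    B = np.zeros((p, p))
    for (a, b), w in zip(spec.edges, betas):
        B[spec.index(b), spec.index(a)] = w
    Psi = np.diag(variances.astype(float))
    for (a, b), c in zip(spec.covariance_pairs, covs):
        i, j = spec.index(a), spec.index(b)
        Psi[i, j] = Psi[j, i] = c
    return B, Psi


def implied_covariance(spec: PathModelSpec, params: dict) -> np.ndarray:
    """Sigma(theta) for explicit parameter values.

    ``params`` holds ``beta`` (edge -> coefficient), ``variance``
    (variable -> exogenous/residual variance) and optional ``covariance``
    (pair -> value) mappings.
    """
    betas = np.array([params["beta"][e] for e in spec.edges], dtype=float)
    variances = np.array([params["variance"][v] for v in spec.variables], dtype=float)
    covs = np.array(
        [params.get("covariance", {}).get(pr, 0.0) for pr in spec.covariance_pairs], dtype=float
    )
    B, Psi = _matrices(spec, betas, variances, covs)
    A = np.linalg.inv(np.eye(spec.p) - B)  # invertible for any acyclic B
    return A @ Psi @ A.T


# ---------------------------------------------------------------------------
# ML fitting


def _unpack(spec: PathModelSpec, theta: np.ndarray):
    m = len(spec.edges)
    p = spec.p
    return theta[:m], np.exp(theta[m : m + p]), theta[m + p :]


def _objective(spec: PathModelSpec, theta: np.ndarray, S: np.ndarray, logdet_S: float):
    """(F_ML, gradient); a large penalty outside the PD region."""
    p = spec.p
    betas, variances, covs = _unpack(spec, theta)
    B, Psi = _matrices(spec, betas, variances, covs)
    A = np.linalg.inv(np.eye(p) - B)
    Sigma = A @ Psi @ A.T
    w = np.linalg.eigvalsh(Sigma)
    if w.min() <= 1e-12:
        return 1e8 * (1.0 + abs(w.min())), np.zeros_like(theta)
    Sigma_inv = np.linalg.inv(Sigma)
    sign, logdet = np.linalg.slogdet(Sigma)
    F = logdet + float(np.trace(S @ Sigma_inv)) - logdet_S - p

    G = Sigma_inv @ (Sigma - S) @ Sigma_inv  # dF/dSigma
    grad = np.empty_like(theta)
    SGA = Sigma @ G @ A
    for k, (a, b) in enumerate(spec.edges):
        grad[k] = 2.0 * SGA[spec.index(a), spec.index(b)]
    H = A.T @ G @ A
    m = len(spec.edges)
    grad[m : m + p] = np.diag(H) * variances  # log-variance chain rule
    for k, (a, b) in enumerate(spec.covariance_pairs):
        i, j = spec.index(a), spec.index(b)
        grad[m + p + k] = H[i, j] + H[j, i]
    return F, grad


def _smart_init(spec: PathModelSpec, S: np.ndarray) -> np.ndarray:
    """Closed-form start: per-equation regression of each endogenous variable
    on its parents, solved directly from S; sample (co)variances elsewhere."""
    p = spec.p
    betas = np.zeros(len(spec.edges))
    variances = np.diag(S).copy()
    endo = sorted({b for _, b in spec.edges})
    for y in endo:
        pars = [a for a, b in spec.edges if b == y]
        pi = [spec.index(a) for a in pars]
        yi = spec.index(y)
        b = np.linalg.solve(S[np.ix_(pi, pi)], S[pi, yi])
        for a, bv in zip(pars, b):
            betas[spec.edges.index((a, y))] = bv
        variances[yi] = max(S[yi, yi] - float(b @ S[pi, yi]), 1e-3 * S[yi, yi])
    covs = np.array([S[spec.index(a), spec.index(b)] for a, b in spec.covariance_pairs])
    return np.concatenate([betas, np.log(variances), covs])


@dataclass
class PathModelFit:
    spec: PathModelSpec
    n_used: int
    raw_coefficients: dict[Edge, float]
    std_coefficients: dict[Edge, float]
    variances: dict[str, float]
    covariances: dict[Edge, float]
    F_ML: float
    chi2: float
    df: int
    p_value: float
    cfi: float
    gfi: float
    agfi: float
    rmsea: float
    converged: bool
    gradient_norm: float
    Sigma_hat: np.ndarray
    S: np.ndarray

    @property
    def indices(self) -> dict[str, float]:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "p_value": self.p_value,
            "cfi": self.cfi,
            "gfi": self.gfi,
            "agfi": self.agfi,
            "rmsea": self.rmsea,
        }

    def criteria_met(self) -> int:
        """How many conventional good-fit criteria the solution satisfies."""
        n = 0
        n += bool(np.isnan(self.p_value) or self.p_value > FIT_CRITERIA["p_value"])
        n += bool(self.cfi > FIT_CRITERIA["cfi"])
        n += bool(self.gfi > FIT_CRITERIA["gfi"])
        n += bool(not np.isnan(self.agfi) and self.agfi > FIT_CRITERIA["agfi"])
        n += bool(np.isnan(self.rmsea) or self.rmsea < FIT_CRITERIA["rmsea"])
        return n

    def summary(self) -> str:
        lines = [f"Path model fit (n = {self.n_used}, df = {self.df})"]
        for e in self.spec.edges:
            lines.append(
                f"  {e[0]} -> {e[1]}: raw {self.raw_coefficients[e]:+.4f}"
                f"  std {self.std_coefficients[e]:+.4f}"
            )
        lines.append(
            f"  chi2({self.df}) = {self.chi2:.3f}, p = {self.p_value:.4f}, "
            f"CFI = {self.cfi:.3f}, GFI = {self.gfi:.3f}, "
            f"AGFI = {self.agfi:.3f}, RMSEA = {self.rmsea:.3f}"
        )
        return "\n".join(lines)


def baseline_chi2(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence-model (diagonal Sigma, free variances) chi2 and df."""
    p = S.shape[0]
    _, logdet_S = np.linalg.slogdet(S)
    F_b = float(np.sum(np.log(np.diag(S)))) - logdet_S
    return (n - 1) * F_b, p * (p + 1) // 2 - p


def fit_indices(
    chi2: float,
    df: int,
    chi2_baseline: float,
    df_baseline: int,
    S: np.ndarray,
    Sigma_hat: np.ndarray,
    n: int,
) -> dict[str, float]:
    """CFI, GFI, AGFI, RMSEA for one fitted model (NaN where undefined)."""
    if df_baseline < df:
        raise ValueError("baseline model must have at least as many df as the target model")
    p = S.shape[0]
    excess = max(chi2 - df, 0.0)
    denom = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    R = np.linalg.solve(Sigma_hat, S)
    gfi = 1.0 - np.trace((R - np.eye(p)) @ (R - np.eye(p))) / np.trace(R @ R)
    if df > 0:
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
        rmsea = float(np.sqrt(excess / (df * (n - 1))))
    else:
        # saturated model: AGFI undefined; RMSEA 0 when the fit is exact,
        # otherwise undefined
        agfi = float("nan")
        rmsea = 0.0 if excess <= 1e-10 else float("nan")
    return {"cfi": cfi, "gfi": float(gfi), "agfi": float(agfi), "rmsea": rmsea}


def fit_ml(
    spec: PathModelSpec,
    S: np.ndarray | pd.DataFrame,
    n: int,
    n_starts: int = 5,
) -> PathModelFit:
    """Fit the path model to a sample covariance matrix by ML."""
    if isinstance(S, pd.DataFrame):
        S = S.loc[list(spec.variables), list(spec.variables)].to_numpy()
    S = np.asarray(S, dtype=float)
    p = spec.p
    if S.shape != (p, p):
        raise ValueError(f"S must be {p}x{p} for this model")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.linalg.eigvalsh(S).min() <= 0:
        raise ValueError("S must be positive definite")
    if n <= p:
        raise ValueError("sample size must exceed the number of variables")

    _, logdet_S = np.linalg.slogdet(S)
    fun = lambda th: _objective(spec, th, S, logdet_S)

    theta0 = _smart_init(spec, S)
    best = None
    for j in range(n_starts):
        start = theta0.copy()
        if j > 0:  # deterministic jitters around the closed-form start
            rng = np.random.default_rng(j)
            start = start + rng.normal(0.0, 0.1, start.shape)
        res = optimize.minimize(
            fun, start, jac=True, method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res

    # Newton polish on the analytic gradient to drive it below tolerance
    theta = best.x
    F, g = fun(theta)
    for _ in range(20):
        if np.linalg.norm(g) < 1e-10:
            break
        J = optimize.approx_fprime(theta, lambda th: fun(th)[1], 1e-7)
        try:
            step = np.linalg.solve(0.5 * (J + J.T), g)
        except np.linalg.LinAlgError:
            break
        trial = theta - step
        F_t, g_t = fun(trial)
        if not np.isfinite(F_t) or F_t > F + 1e-12:
            break
        theta, F, g = trial, F_t, g_t

    grad_norm = float(np.linalg.norm(g))
    converged = grad_norm < 1e-8
    betas, variances, covs = _unpack(spec, theta)
    B, Psi = _matrices(spec, betas, variances, covs)
    A = np.linalg.inv(np.eye(p) - B)
    Sigma = A @ Psi @ A.T

    sd = np.sqrt(np.diag(Sigma))
    raw = {e: float(b) for e, b in zip(spec.edges, betas)}
    std = {
        (a, b): float(w * sd[spec.index(a)] / sd[spec.index(b)]) for (a, b), w in raw.items()
    }
    chi2 = max((n - 1) * F, 0.0)
    df = spec.df
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")
    chi2_b, df_b = baseline_chi2(S, n)
    idx = fit_indices(chi2, df, chi2_b, df_b, S, Sigma, n)

    return PathModelFit(
        spec=spec,
        n_used=n,
        raw_coefficients=raw,
        std_coefficients=std,
        variances={v: float(x) for v, x in zip(spec.variables, variances)},
        covariances={pr: float(c) for pr, c in zip(spec.covariance_pairs, covs)},
        F_ML=float(F),
        chi2=float(chi2),
        df=df,
        p_value=p_value,
        converged=bool(converged),
        gradient_norm=grad_norm,
        Sigma_hat=Sigma,
        S=S,
        **idx,
    )


def compare_models(
    fit1: PathModelFit, fit2: PathModelFit, names: tuple[str, str] = ("model_1", "model_2")
) -> dict:
    """Side-by-side fit indices and a preferred-model call.

    Preference: the model meeting more of the conventional criteria
    (chi2 p > 0.05, CFI/GFI/AGFI > 0.95, RMSEA < 0.08); ties broken by CFI;
    exact ties reported as such.
    """
    if fit1.n_used != fit2.n_used:
        raise ValueError("fits use different sample sizes; not comparable")
    c1, c2 = fit1.criteria_met(), fit2.criteria_met()
    if (c1, fit1.cfi) > (c2, fit2.cfi):
        preferred = names[0]
    elif (c2, fit2.cfi) > (c1, fit1.cfi):
        preferred = names[1]
    else:
        preferred = "tie"
    return {
        names[0]: {**fit1.indices, "criteria_met": c1},
        names[1]: {**fit2.indices, "criteria_met": c2},
        "preferred": preferred,
    }


# ---------------------------------------------------------------------------
# canonical model specs and a tiny text DSL


def model_without_ilv() -> PathModelSpec:
    """Five-variable model: age drives WML burden and white-matter integrity,
    which with education drive cognition; no ischemic-lesion path."""
    return PathModelSpec(
        variables=("age", "education", "wml", "nawm_integrity", "cognition"),
        edges=(
            ("education", "cognition"),
            ("age", "wml"),
            ("age", "nawm_integrity"),
            ("wml", "cognition"),
            ("nawm_integrity", "cognition"),
        ),
        exogenous_covariances=(("age", "education"),),
        residual_covariances=(("wml", "nawm_integrity"),),
    )


def model_with_ilv() -> PathModelSpec:
    """Six-variable variant adding the acute ischemic lesion volume: WML
    predicts ILV, and ILV gets a direct path to cognition."""
    base = model_without_ilv()
    return PathModelSpec(
        variables=base.variables[:4] + ("ilv",) + base.variables[4:],
        edges=base.edges + (("wml", "ilv"), ("ilv", "cognition")),
        exogenous_covariances=base.exogenous_covariances,
        residual_covariances=base.residual_covariances,
    )


def model_from_yaml(text: str) -> PathModelSpec:
    """Load a model spec from YAML::

        variables: [age, education, wml, nawm_integrity, cognition]
        edges:
          - age -> wml
          - wml -> cognition
        covariances:
          - wml ~~ nawm_integrity
    """
    import yaml

    doc = yaml.safe_load(text)
    lines = [f"var {' '.join(doc.get('variables', []))}"]
    lines += [f"edge {e}" for e in doc.get("edges", [])]
    lines += [f"cov {c}" for c in doc.get("covariances", [])]
    return parse_model_text("\n".join(lines))


def parse_model_text(text: str) -> PathModelSpec:
    """Parse a small model DSL::

        var age education wml cognition
        edge age -> wml
        edge wml -> cognition
        cov wml ~~ nawm_integrity

    ``var`` lines are optional; undeclared names are collected in order of
    appearance. Covariance pairs between two exogenous variables are recorded
    as exogenous covariances, all others as residual covariances.
    """
    variables: list[str] = []
    edges: list[Edge] = []
    covs: list[Edge] = []

    def note(name: str) -> None:
        if name not in variables:
            variables.append(name)

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if parts[0] == "var":
            for name in parts[1:]:
                note(name)
        elif parts[0] == "edge" and len(parts) == 4 and parts[2] == "->":
            note(parts[1]), note(parts[3])
            edges.append((parts[1], parts[3]))
        elif parts[0] == "cov" and len(parts) == 4 and parts[2] == "~~":
            note(parts[1]), note(parts[3])
            covs.append((parts[1], parts[3]))
        else:
            raise ValueError(f"cannot parse model line: {raw!r}")
    endo = {b for _, b in edges}
    exo_covs = tuple(pr for pr in covs if pr[0] not in endo and pr[1] not in endo)
    res_covs = tuple(pr for pr in covs if pr not in exo_covs)
    return PathModelSpec(tuple(variables), tuple(edges), exo_covs, res_covs)
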