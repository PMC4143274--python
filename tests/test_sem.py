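"""Path analysis: implied covariance algebra, ML fit, indices, comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

import strokesem as sk
from strokesem.sem import (
    PathModelSpec,
    baseline_chi2,
    fit_indices,
    model_with_ilv,
    model_without_ilv,
    parse_model_text,
)

MODEL2_PATHS = {
    ("education", "cognition"): 0.328,
    ("age", "wml"): 0.306,
    ("age", "nawm_integrity"): 0.370,
    ("wml", "cognition"): -0.231,
    ("nawm_integrity", "cognition"): -0.176,
}


def simulate_model2(n, seed):
    return sk.simulate_cohort(
        sk.CohortModelSpec(
            n_subjects=n,
            variables=("age", "education", "wml", "nawm_integrity", "cognition"),
            path_coefficients=MODEL2_PATHS,
            exogenous_correlations={("age", "education"): -0.10},
            seed=seed,
        )
    )


class TestImpliedCovariance:
    def test_no_edges_gives_psi(self):
        spec = PathModelSpec(("x", "y"), ())
        sigma = sk.implied_covariance(
            spec, {"beta": {}, "variance": {"x": 2.0, "y": 3.0}}
        )
        np.testing.assert_allclose(sigma, np.diag([2.0, 3.0]))

    def test_single_edge_closed_form(self):
        spec = PathModelSpec(("x", "y"), (("x", "y"),))
        b, psi = 0.7, 0.51
        sigma = sk.implied_covariance(
            spec, {"beta": {("x", "y"): b}, "variance": {"x": 1.0, "y": psi}}
        )
        np.testing.assert_allclose(sigma, [[1.0, b], [b, b**2 + psi]], atol=1e-14)

    def test_chain_matches_monte_carlo_oracle(self):
        spec = PathModelSpec(("a", "b", "c"), (("a", "b"), ("b", "c")))
        b1, b2 = 0.6, -0.4
        params = {
            "beta": {("a", "b"): b1, ("b", "c"): b2},
            "variance": {"a": 1.0, "b": 0.64, "c": 0.8},
        }
        sigma = sk.implied_covariance(spec, params)
        # brute-force simulation of the linear system
        rng = np.random.default_rng(0)
        n = 400_000
        a = rng.normal(size=n)
        bb = b1 * a + np.sqrt(0.64) * rng.normal(size=n)
        c = b2 * bb + np.sqrt(0.8) * rng.normal(size=n)
        mc = np.cov(np.stack([a, bb, c]))
        np.testing.assert_allclose(sigma, mc, atol=5 / np.sqrt(n))
        assert sigma[0, 2] == pytest.approx(b1 * b2, abs=1e-14)


class TestSpecValidation:
    def test_cycles_duplicates_and_unknown_names_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            PathModelSpec(("x", "y"), (("x", "y"), ("y", "x")))
        with pytest.raises(ValueError, match="duplicate"):
            PathModelSpec(("x", "y"), (("x", "y"), ("x", "y")))
        with pytest.raises(ValueError, match="unknown"):
            PathModelSpec(("x",), (("x", "z"),))

    def test_df_matches_brute_force_parameter_count(self):
        for spec in (model_without_ilv(), model_with_ilv()):
            p = len(spec.variables)
            n_params = (
                len(spec.edges)
                + p
                + len(spec.exogenous_covariances)
                + len(spec.residual_covariances)
            )
            assert spec.df == p * (p + 1) // 2 - n_params

    def test_documented_five_variable_model_df_is_3(self):
        assert model_without_ilv().df == 3

    def test_dsl_round_trip(self):
        text = """
        var age education wml nawm_integrity cognition
        edge education -> cognition
        edge age -> wml
        edge age -> nawm_integrity
        edge wml -> cognition
        edge nawm_integrity -> cognition
        cov age ~~ education
        cov wml ~~ nawm_integrity
        """
        assert parse_model_text(text) == model_without_ilv()
        with pytest.raises(ValueError, match="cannot parse"):
            parse_model_text("edge a => b")

    def test_yaml_spec_loads_the_same_model(self):
        from strokesem.sem import model_from_yaml

        yaml_text = """
        variables: [age, education, wml, nawm_integrity, cognition]
        edges:
          - education -> cognition
          - age -> wml
          - age -> nawm_integrity
          - wml -> cognition
          - nawm_integrity -> cognition
        covariances:
          - age ~~ education
          - wml ~~ nawm_integrity
        """
        assert model_from_yaml(yaml_text) == model_without_ilv()


class TestFitML:
    def test_saturated_model_fits_perfectly(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 2))
        x[:, 1] += 0.5 * x[:, 0]
        S = np.cov(x.T)
        spec = PathModelSpec(("x", "y"), (("x", "y"),))
        assert spec.df == 0
        fit = sk.fit_ml(spec, S, n=200)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0
        np.testing.assert_allclose(fit.Sigma_hat, S, atol=1e-8)

    def test_single_predictor_standardized_beta_equals_pearson_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = 0.4 * x + rng.normal(size=300)
        S = np.cov(np.stack([x, y]))
        fit = sk.fit_ml(PathModelSpec(("x", "y"), (("x", "y"),)), S, n=300)
        r = np.corrcoef(x, y)[0, 1]
        assert fit.std_coefficients[("x", "y")] == pytest.approx(r, abs=1e-10)

    def test_recovers_generating_coefficients_and_matches_independent_minimizer(self):
        n = 100_000
        df = simulate_model2(n, seed=10)
        spec = model_without_ilv()
        S = df[list(spec.variables)].cov().to_numpy()
        fit = sk.fit_ml(spec, S, n=n)
        assert fit.converged and fit.gradient_norm < 1e-8
        for edge, true in MODEL2_PATHS.items():
            assert fit.std_coefficients[edge] == pytest.approx(true, abs=3 * 1.2 / np.sqrt(n))

        # independent oracle: the same ML discrepancy written and minimized
        # separately (Nelder-Mead, different parameterization: raw variances)
        idx = {v: i for i, v in enumerate(spec.variables)}
        p = len(spec.variables)

        def sigma_of(theta):
            B = np.zeros((p, p))
            for k, (a, b) in enumerate(spec.edges):
                B[idx[b], idx[a]] = theta[k]
            Psi = np.diag(np.abs(theta[len(spec.edges) : len(spec.edges) + p]))
            for k, (a, b) in enumerate(spec.covariance_pairs):
                Psi[idx[a], idx[b]] = Psi[idx[b], idx[a]] = theta[len(spec.edges) + p + k]
            A = np.linalg.inv(np.eye(p) - B)
            return A @ Psi @ A.T

        def discrepancy(theta):
            sigma = sigma_of(theta)
            w = np.linalg.eigvalsh(sigma)
            if w.min() <= 0:
                return 1e6
            return (
                np.linalg.slogdet(sigma)[1]
                + np.trace(S @ np.linalg.inv(sigma))
                - np.linalg.slogdet(S)[1]
                - p
            )

        x0 = np.concatenate(
            [
                [fit.raw_coefficients[e] + 0.01 for e in spec.edges],
                [fit.variances[v] * 1.05 for v in spec.variables],
                [fit.covariances[c] + 0.01 for c in spec.covariance_pairs],
            ]
        )
        res = optimize.minimize(
            discrepancy, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
        )
        for k, e in enumerate(spec.edges):
            assert fit.raw_coefficients[e] == pytest.approx(res.x[k], abs=1e-3)
        assert fit.F_ML == pytest.approx(res.fun, abs=1e-8)

    def test_standardized_coefficients_invariant_to_affine_rescaling(self):
        df = simulate_model2(2000, seed=11)
        spec = model_without_ilv()
        S1 = df[list(spec.variables)].cov().to_numpy()
        df2 = df.copy()
        df2["wml"] = df2["wml"] * 1000.0 + 5.0
        df2["cognition"] = df2["cognition"] * 15.0 + 100.0
        S2 = df2[list(spec.variables)].cov().to_numpy()
        f1 = sk.fit_ml(spec, S1, n=2000)
        f2 = sk.fit_ml(spec, S2, n=2000)
        for e in spec.edges:
            assert f1.std_coefficients[e] == pytest.approx(f2.std_coefficients[e], abs=1e-7)

    def test_invalid_inputs_rejected(self):
        spec = PathModelSpec(("x", "y"), (("x", "y"),))
        with pytest.raises(ValueError, match="symmetric"):
            sk.fit_ml(spec, np.array([[1.0, 0.5], [0.2, 1.0]]), n=50)
        with pytest.raises(ValueError, match="positive definite"):
            sk.fit_ml(spec, np.array([[1.0, 1.1], [1.1, 1.0]]), n=50)
        with pytest.raises(ValueError, match="sample size"):
            sk.fit_ml(spec, np.eye(2), n=2)


class TestFitIndices:
    def test_formulas_match_hand_computation(self):
        df142 = simulate_model2(142, seed=12)
        S = df142[["age", "education", "wml", "nawm_integrity", "cognition"]].cov().to_numpy()
        n, df = 142, 3
        chi2 = 45.89
        chi2_b, df_b = baseline_chi2(S, n)
        sigma_hat = S * 1.02 + 0.001 * np.eye(5)
        got = fit_indices(chi2, df, chi2_b, df_b, S, sigma_hat, n)
        p = 5
        expected_cfi = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)
        R = np.linalg.inv(sigma_hat) @ S
        expected_gfi = 1 - np.trace((R - np.eye(p)) @ (R - np.eye(p))) / np.trace(R @ R)
        assert got["cfi"] == pytest.approx(max(min(expected_cfi, 1), 0), abs=1e-10)
        assert got["gfi"] == pytest.approx(expected_gfi, abs=1e-10)
        assert got["agfi"] == pytest.approx(
            1 - (p * (p + 1) / (2 * df)) * (1 - expected_gfi), abs=1e-10
        )
        assert got["rmsea"] == pytest.approx(np.sqrt((chi2 - df) / (df * (n - 1))), abs=1e-10)

    def test_perfect_fit_gives_unit_gfi_and_zero_rmsea(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        got = fit_indices(3.0, 3, 50.0, 10, S, S, 100)
        assert got["gfi"] == pytest.approx(1.0, abs=1e-12)
        assert got["rmsea"] == 0.0  # chi2 == df limit


class TestCompareModels:
    def test_headline_cfi_contrast_prefers_the_better_model(self):
        df = simulate_model2(142, seed=13)
        spec = model_without_ilv()
        S = df[list(spec.variables)].cov()
        good = sk.fit_ml(spec, S, n=142)
        from dataclasses import replace

        bad = replace(good, cfi=0.092, gfi=0.873, agfi=0.388, rmsea=0.28, p_value=1e-6)
        good = replace(good, cfi=0.9, gfi=0.973, agfi=0.865, rmsea=0.11, p_value=0.053)
        report = sk.compare_models(bad, good)
        assert report["preferred"] == "model_2"

    def test_identical_fits_tie(self):
        df = simulate_model2(142, seed=14)
        spec = model_without_ilv()
        fit = sk.fit_ml(spec, df[list(spec.variables)].cov(), n=142)
        assert sk.compare_models(fit, fit)["preferred"] == "tie"

    def test_different_sample_sizes_rejected(self):
        df = simulate_model2(142, seed=15)
        spec = model_without_ilv()
        f1 = sk.fit_ml(spec, df[list(spec.variables)].cov(), n=142)
        f2 = sk.fit_ml(spec, df[list(spec.variables)].cov(), n=100)
        with pytest.raises(ValueError, match="sample sizes"):
            sk.compare_models(f1, f2)
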