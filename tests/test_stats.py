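"""Inferential machinery: regressions, ANCOVA, path fits, MI, reliability."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from stopnet import presets
from stopnet.cohort import generate_from_correlation, generate_from_path_model, inject_missingness
from stopnet.pathmodel import PathModelSpec
from stopnet.stats import (
    CollinearityError,
    cramers_v,
    cronbach_alpha,
    fit_path_model,
    hierarchical_regression,
    impute_and_pool,
    one_tailed_p,
    quartile_ancova,
    rubin_pool,
    significance_mark,
)


class TestHierarchicalRegression:
    def test_single_predictor_beta_equals_pearson_r(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        y = 0.4 * x + rng.normal(size=500)
        df = pd.DataFrame({"x": x, "y": y})
        reg = hierarchical_regression(df, "y", blocks=[["x"]])
        r = np.corrcoef(x, y)[0, 1]
        assert reg.steps[0].beta["x"] == pytest.approx(r, abs=1e-12)

    def test_orthogonal_predictors_decompose_r_squared(self):
        # Exactly orthogonal standardized predictors: beta_i = r_i and
        # R^2 = r1^2 + r2^2 (normal-equations oracle).
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(400, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        x1, x2 = q[:, 0], q[:, 1]
        y = 0.5 * x1 - 0.3 * x2 + rng.normal(size=400)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        reg = hierarchical_regression(df, "y", blocks=[["x1", "x2"]])
        step = reg.steps[0]
        r1 = np.corrcoef(x1, y)[0, 1]
        r2 = np.corrcoef(x2, y)[0, 1]
        assert step.beta["x1"] == pytest.approx(r1, abs=1e-10)
        assert step.beta["x2"] == pytest.approx(r2, abs=1e-10)
        assert step.r_squared == pytest.approx(r1**2 + r2**2, abs=1e-10)

    def test_adjusted_r_squared_identity_and_monotone_r2(self):
        tab = generate_from_correlation(presets.study_correlation_matrix(), 2_000, seed=3)
        reg = hierarchical_regression(
            tab,
            "n2",
            blocks=[["inattention_child", "hyperactivity_child"]],
            covariates=["mother_education"],
        )
        s1, s2 = reg.steps
        assert s2.r_squared >= s1.r_squared
        n, k = reg.n, len(s2.predictors)
        expected_adj = 1 - (1 - s2.r_squared) * (n - 1) / (n - k - 1)
        assert s2.adj_r_squared == pytest.approx(expected_adj, abs=1e-12)
        assert s2.delta_r_squared == pytest.approx(s2.r_squared - s1.r_squared)

    def test_recovers_generating_coefficients(self):
        spec, exog = presets.n2_regression_model()
        tab = generate_from_path_model(spec, exog, 50_000, seed=4)
        reg = hierarchical_regression(
            tab,
            "n2",
            blocks=[["inattention_child", "hyperactivity_child"]],
            covariates=["mother_education"],
        )
        step2 = reg.steps[-1]
        assert step2.beta["inattention_child"] == pytest.approx(0.31, abs=0.03)
        assert step2.beta["hyperactivity_child"] == pytest.approx(0.0, abs=0.03)
        assert step2.beta["mother_education"] == pytest.approx(-0.25, abs=0.03)

    def test_collinear_block_is_an_error(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "x2": 2 * x, "y": rng.normal(size=100)})
        with pytest.raises(CollinearityError, match="x"):
            hierarchical_regression(df, "y", blocks=[["x", "x2"]])


class TestOneTailed:
    @pytest.mark.parametrize("estimate, direction, expected", [
        (0.5, 1.0, 0.02),     # sign matches: half
        (-0.5, 1.0, 0.98),    # sign mismatch: 1 - half
        (0.5, None, 0.02),    # no declared direction: half
    ])
    def test_convention(self, estimate, direction, expected):
        assert one_tailed_p(estimate, 0.04, direction) == pytest.approx(expected)

    def test_marks(self):
        assert [significance_mark(p) for p in (0.0005, 0.005, 0.04, 0.09, 0.5)] == [
            "***", "**", "*", "+", ""
        ]


def _ancova_fixture():
    # 12 rows, grouping variable with three values per quartile, known
    # covariate; used for the brute-force sums-of-squares oracle.
    return pd.DataFrame(
        {
            "group_score": [1, 2, 3, 11, 12, 13, 21, 22, 23, 31, 32, 33],
            "covariate": [0.1, -0.2, 0.3, 0.0, 0.2, -0.1, 0.4, -0.3, 0.1, 0.2, -0.2, 0.0],
            "outcome": [-3.1, -2.7, -3.4, -0.8, -1.1, -0.6, -0.9, -1.3, -0.5, -1.0, -0.7, -1.2],
        }
    )


class TestQuartileAncova:
    def test_null_case_f_near_zero(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "g": np.tile([1, 2, 3, 4], 250),
                "cov": rng.normal(size=1000),
                "y": np.zeros(1000),
            }
        )
        df["y"] = rng.normal(size=1000)  # outcome unrelated to group
        res = quartile_ancova(df, "y", "g", "cov")
        assert res.omnibus_eta_sq_partial < 0.02
        assert res.omnibus_p > 0.01

    def test_matches_brute_force_ss_decomposition(self):
        df = _ancova_fixture()
        res = quartile_ancova(df, "outcome", "group_score", "covariate")
        assert res.group_sizes == (3, 3, 3, 3)

        # Oracle: explicit least-squares projections.
        y = df["outcome"].to_numpy()
        cov = df["covariate"].to_numpy()
        g = np.searchsorted(np.quantile(df["group_score"], [0.25, 0.5, 0.75]),
                            df["group_score"], side="left")
        X_full = np.column_stack(
            [np.ones(12), cov] + [(g == k).astype(float) for k in (1, 2, 3)]
        )
        X_red = np.column_stack([np.ones(12), cov])

        def sse(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return r @ r

        sse_full, sse_red = sse(X_full), sse(X_red)
        df_err = 12 - 5
        f_oracle = ((sse_red - sse_full) / 3) / (sse_full / df_err)
        eta_oracle = (sse_red - sse_full) / (sse_red - sse_full + sse_full)
        assert res.omnibus_f == pytest.approx(f_oracle, rel=1e-10)
        assert res.omnibus_eta_sq_partial == pytest.approx(eta_oracle, rel=1e-10)
        assert res.mse == pytest.approx(sse_full / df_err, rel=1e-10)
        assert res.omnibus_df == (3, df_err)

    def test_lowest_quartile_shift_drives_contrast(self):
        # Only the lowest quartile shifted -1 SD: the planned contrast is
        # significant and carries the omnibus effect.
        rng = np.random.default_rng(7)
        n = 10_000
        g = rng.normal(size=n)
        cov = rng.normal(size=n)
        y = rng.normal(size=n)
        q1 = g <= np.quantile(g, 0.25)
        y[q1] -= 1.0
        df = pd.DataFrame({"g": g, "cov": cov, "y": y})
        res = quartile_ancova(df, "y", "g", "cov")
        assert res.contrast_p < 1e-6
        assert res.omnibus_p < 1e-6
        assert res.group_adjusted_means[0] == min(res.group_adjusted_means)
        upper = res.group_adjusted_means[1:]
        assert max(upper) - min(upper) < 0.15  # top three quartiles alike

    def test_too_few_distinct_values(self):
        df = pd.DataFrame({"g": [1, 1, 2, 2], "cov": [0, 1, 0, 1], "y": [0, 1, 2, 3]})
        with pytest.raises(ValueError):
            quartile_ancova(df, "y", "g", "cov")


class TestPathFit:
    def test_saturated_model_fits_perfectly(self):
        tab = generate_from_correlation(np.eye(3) + 0.3 * (1 - np.eye(3)), 2_000, seed=8)
        spec = PathModelSpec(arrows=(("v0", "v2"), ("v1", "v2"), ("v0", "v1")))
        fit = fit_path_model(tab, spec)
        assert fit.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0
        assert fit.srmr == pytest.approx(0.0, abs=1e-9)

    def test_equations_match_closed_form_partial_regression(self):
        # Independent oracle: per-equation coefficients from the inverse of
        # the predictor correlation block, computed directly.
        tab = generate_from_correlation(
            np.array([[1.0, 0.4, 0.3], [0.4, 1.0, 0.5], [0.3, 0.5, 1.0]]),
            5_000,
            seed=9,
        )
        spec = PathModelSpec(arrows=(("v0", "v2"), ("v1", "v2")))
        fit = fit_path_model(tab, spec)
        S = tab.data.corr()
        Spp = S.loc[["v0", "v1"], ["v0", "v1"]].to_numpy()
        spy = S.loc[["v0", "v1"], "v2"].to_numpy()
        oracle = np.linalg.solve(Spp, spy)
        assert fit.coefficient("v0", "v2") == pytest.approx(oracle[0], abs=1e-10)
        assert fit.coefficient("v1", "v2") == pytest.approx(oracle[1], abs=1e-10)

    def test_concurrent_model_recovers_printed_paths(self):
        spec, exog = presets.concurrent_path_model()
        tab = generate_from_path_model(spec, exog, 50_000, seed=10)
        fit = fit_path_model(tab, spec)
        assert fit.coefficient("effortful_control", "n2") == pytest.approx(-0.33, abs=0.03)
        assert fit.coefficient("father_inattention", "n2") == pytest.approx(0.35, abs=0.03)
        assert fit.cfi > 0.99
        assert fit.rmsea < 0.02

    def test_indirect_effect_product_and_bootstrap_sobel(self):
        # Chain a=0.5, b=0.4: indirect effect 0.20; first-order Sobel SE
        # must agree with a nonparametric bootstrap SE within 10%.
        spec = PathModelSpec(
            arrows=(("x", "m"), ("m", "y")),
            coefficients={("x", "m"): 0.5, ("m", "y"): 0.4},
        )
        tab = generate_from_path_model(spec, None, 50_000, seed=11)
        fit = fit_path_model(tab, spec)
        chain = next(e for e in fit.indirect_effects if e.chain == ("x", "m", "y"))
        assert chain.effect == pytest.approx(0.20, abs=0.01)

        rng = np.random.default_rng(12)
        z = ((tab.data - tab.data.mean()) / tab.data.std(ddof=1)).to_numpy()
        x, m, y = z[:, 0], z[:, 1], z[:, 2]
        n = len(x)
        boots = []
        for _ in range(200):
            idx = rng.integers(n, size=n)
            xb, mb, yb = x[idx], m[idx], y[idx]
            a = np.dot(xb, mb) / np.dot(xb, xb)
            b = np.dot(mb, yb) / np.dot(mb, mb)
            boots.append(a * b)
        boot_se = np.std(boots, ddof=1)
        assert chain.se == pytest.approx(boot_se, rel=0.10)

    def test_sobel_interval_coverage(self):
        # 95% normal-theory CIs for a*b cover the true 0.20 in >= 90/100
        # seeded replications at n = 2,000.
        spec = PathModelSpec(
            arrows=(("x", "m"), ("m", "y")),
            coefficients={("x", "m"): 0.5, ("m", "y"): 0.4},
        )
        covered = 0
        for s in range(100):
            tab = generate_from_path_model(spec, None, 2_000, seed=500 + s)
            fit = fit_path_model(tab, spec)
            chain = fit.indirect_effects[0]
            lo = chain.effect - 1.96 * chain.se
            hi = chain.effect + 1.96 * chain.se
            covered += lo <= 0.20 <= hi
        assert covered >= 90

    def test_fit_indices_limit_under_correct_specification(self):
        # Correctly specified non-saturated model at large n: RMSEA -> 0,
        # CFI -> 1.
        spec, exog = presets.concurrent_path_model()
        tab = generate_from_path_model(spec, exog, 100_000, seed=13)
        fit = fit_path_model(tab, spec)
        assert fit.df > 0
        assert fit.rmsea < 0.01
        assert fit.cfi > 0.999
        assert fit.srmr < 0.01


class TestMultipleImputation:
    def test_rubin_toy_arithmetic(self):
        pooled = rubin_pool("r", [0.1, 0.2, 0.3], [0.01, 0.01, 0.01])
        assert pooled.estimate == pytest.approx(0.2)
        assert pooled.within == pytest.approx(0.01)
        assert pooled.between == pytest.approx(0.01)
        assert pooled.total == pytest.approx(0.01 + (1 + 1 / 3) * 0.01)
        assert pooled.total == pytest.approx(0.023333333333333334)

    def test_no_missing_cells_degenerate_pooling(self):
        tab = generate_from_correlation(np.eye(2), 200, seed=14)

        def analysis(df):
            r = df.corr().iloc[0, 1]
            return {"r": (r, (1 - r**2) ** 2 / (len(df) - 1))}

        pooled = impute_and_pool(tab, analysis, m=5, seed=1)["r"]
        assert pooled.between == 0.0
        assert pooled.estimate == pytest.approx(tab.data.corr().iloc[0, 1])

    def test_pooled_correlation_unbiased_under_mcar(self):
        # 10% MCAR on one variable, true r = 0.3: pooled estimate unbiased
        # within +/-0.02 averaged over 50 replications (n=5,000, m=20).
        R = np.eye(2)
        R[0, 1] = R[1, 0] = 0.3

        def analysis(df):
            r = df.corr().iloc[0, 1]
            return {"r": (r, (1 - r**2) ** 2 / (len(df) - 1))}

        estimates = []
        for s in range(50):
            tab = generate_from_correlation(R, 5_000, seed=700 + s)
            gappy = inject_missingness(tab, {"v0": 0.10}, seed=800 + s)
            pooled = impute_and_pool(gappy, analysis, m=20, seed=900 + s)["r"]
            estimates.append(pooled.estimate)
        assert np.mean(estimates) == pytest.approx(0.3, abs=0.02)

    def test_fully_missing_variable_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_and_pool(df, lambda d: {"m": (d["b"].mean(), 0.1)}, m=2, seed=0)


class TestReliabilityAndAssociation:
    def test_alpha_identical_items_is_one(self):
        x = np.tile(np.arange(10.0), (3, 1)).T
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_alpha_matches_definitional_formula_on_fixed_table(self):
        x = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 4.0], [4.0, 3.0]])
        k = 2
        expected = k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / x.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(x) == pytest.approx(expected)

    def test_alpha_of_equicorrelated_subscales(self):
        # Four subscales with common r from the Spearman-Brown relation
        # alpha = k r / (1 + (k-1) r): alpha = 0.83 -> r ~= 0.5497.
        r = 0.83 / (4 - 3 * 0.83)
        R = np.full((4, 4), r)
        np.fill_diagonal(R, 1.0)
        tab = generate_from_correlation(R, 20_000, seed=15)
        assert cronbach_alpha(tab.data.to_numpy()) == pytest.approx(0.83, abs=0.01)

    def test_alpha_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.zeros((5, 3)))

    def test_cramers_v_perfect_and_independent(self):
        assert cramers_v(np.array([[20, 0], [0, 30]])) == pytest.approx(1.0)
        outer = np.outer([10, 20], [5, 15])
        assert cramers_v(outer) == pytest.approx(0.0, abs=1e-12)

    def test_cramers_v_matches_hand_chi_square(self):
        table = np.array([[20, 10, 3, 10], [40, 13, 10, 12]])
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert cramers_v(table) == pytest.approx(np.sqrt(chi2 / n), abs=1e-12)

    def test_cramers_v_invalid_tables(self):
        with pytest.raises(ValueError):
            cramers_v(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            cramers_v(np.array([[1, 2]]))
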