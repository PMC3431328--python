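"""Least-squares engine against independent oracles (normal equations,
statsmodels), plus adjusted means and partial correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidgrs.regress import (
    build_design,
    fit_ols,
    ls_means,
    nested_f_test,
    partial_r,
)


def _random_instance(rng, n=None, p=None):
    n = n or int(rng.integers(15, 60))
    p = p or int(rng.integers(2, 6))
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = X @ rng.normal(size=p) + rng.normal(size=n)
    return X, y


class TestFit:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        X = np.column_stack([np.ones(10), x])
        fit = fit_ols(X, 2.0 * x)
        assert fit.params == pytest.approx([0.0, 2.0], abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_everywhere(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        for _ in range(50):
            X, y = _random_instance(rng)
            fit = fit_ols(X, y)
            ref = sm.OLS(y, X).fit()
            assert np.allclose(fit.params, ref.params, rtol=1e-8)
            assert np.allclose(fit.se, ref.bse, rtol=1e-8)
            assert np.allclose(fit.pvalues, ref.pvalues, rtol=1e-6, atol=1e-12)
            assert fit.df_resid == ref.df_resid

    def test_duplicated_column_named_in_error(self):
        df = pd.DataFrame({"intercept": 1.0, "a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(df, np.arange(4.0))

    def test_missing_values_rejected(self):
        X = np.column_stack([np.ones(5), [1, 2, np.nan, 4, 5]])
        with pytest.raises(ValueError, match="[Mm]issing"):
            fit_ols(X, np.arange(5.0))

    def test_ci_coverage_nominal(self):
        # 95% normal-theory CIs for a slope cover the truth at ~nominal rate
        rng = np.random.default_rng(11)
        hits = 0
        n_sims, n = 1000, 500
        for _ in range(n_sims):
            x = rng.normal(size=n)
            y = 1.0 + 0.5 * x + rng.normal(size=n)
            fit = fit_ols(np.column_stack([np.ones(n), x]), y)
            lo = fit.params[1] - 1.959963984540054 * fit.se[1]
            hi = fit.params[1] + 1.959963984540054 * fit.se[1]
            hits += lo <= 0.5 <= hi
        assert 0.92 <= hits / n_sims <= 0.98


class TestNestedF:
    def test_identical_models(self):
        rng = np.random.default_rng(0)
        X, y = _random_instance(rng)
        fit = fit_ols(X, y)
        assert nested_f_test(fit, fit) == (0.0, 1.0)

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(1)
        X, y = _random_instance(rng, n=30, p=3)
        full = fit_ols(pd.DataFrame(X, columns=["i", "a", "b"]), y)
        other = fit_ols(pd.DataFrame(X, columns=["i", "a", "c"]), y)
        assert set(other.terms) - set(full.terms)
        with pytest.raises(ValueError, match="nested"):
            nested_f_test(full, other)

    def test_matches_statsmodels_f(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
        y = X[:, 1] * 0.4 + rng.normal(size=n)
        full = fit_ols(pd.DataFrame(X, columns=list("iabc")), y)
        red = fit_ols(pd.DataFrame(X[:, :2], columns=list("ia")), y)
        f, p = nested_f_test(full, red)
        ref_f, ref_p, _ = (
            sm.OLS(y, X).fit().compare_f_test(sm.OLS(y, X[:, :2]).fit())
        )
        assert f == pytest.approx(ref_f, rel=1e-10)
        assert p == pytest.approx(ref_p, rel=1e-10)

    def test_null_extra_term_p_uniform(self):
        # adding a pure-noise column: p ~ U(0,1) across replicates
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(400):
            n = 100
            x = rng.normal(size=(n, 2))
            y = rng.normal(size=n)
            full = fit_ols(np.column_stack([np.ones(n), x]), y)
            red = fit_ols(np.column_stack([np.ones(n), x[:, :1]]), y)
            ps.append(nested_f_test(full, red)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_detects_real_two_df_effect(self):
        # 3-level factor with a 0.5-SD spread is essentially always found
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(50)        :
            n = 1000
            g = rng.integers(0, 3, size=n)
            y = np.where(g == 1, 0.25, np.where(g == 2, -0.25, 0.0)) + rng.normal(size=n)
            X_full = np.column_stack(
                [np.ones(n), (g == 1).astype(float), (g == 2).astype(float)]
            )
            full = fit_ols(X_full, y)
            red = fit_ols(np.ones((n, 1)), y)
            hits += nested_f_test(full, red)[1] < 0.05
        assert hits >= 49


class TestLSMeans:
    def test_single_group_no_covariates_is_arithmetic_mean(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 6.0], "g": "a"})
        am = ls_means(df, "y", "g")
        assert am.mean("a") == pytest.approx(3.0)

    def test_ln_scale_constant_back_transforms_exactly(self):
        df = pd.DataFrame({"y": np.log([7.0] * 5), "g": "a"})
        am = ls_means(df, "y", "g", scale="ln")
        assert am.mean("a") == pytest.approx(7.0, rel=1e-12)

    def test_balanced_design_with_centered_covariate(self):
        # under balance, adjusted means equal raw group means
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        x = x - x.mean()
        g = np.array(["a"] * 10 + ["b"] * 10)
        x = np.concatenate([x[:10] - x[:10].mean(), x[10:] - x[10:].mean()])
        y = np.where(g == "b", 2.0, 0.0) + 0.5 * x + rng.normal(size=20)
        df = pd.DataFrame({"y": y, "g": g, "x": x})
        am = ls_means(df, "y", "g", covariates=["x"])
        assert am.mean("a") == pytest.approx(y[g == "a"].mean(), abs=1e-10)
        assert am.mean("b") == pytest.approx(y[g == "b"].mean(), abs=1e-10)

    def test_proportion_weighted_average_recovers_overall_mean(self):
        rng = np.random.default_rng(4)
        n = 60
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "g": rng.choice(["a", "b", "c"], size=n, p=[0.5, 0.3, 0.2]),
            }
        )
        am = ls_means(df, "y", "g")
        props = df["g"].value_counts(normalize=True)
        weighted = sum(am.mean(l) * props[l] for l in props.index)
        assert weighted == pytest.approx(df["y"].mean(), abs=1e-10)

    def test_ci_brackets_mean(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"y": rng.normal(size=40), "g": ["a", "b"] * 20, "x": rng.normal(size=40)}
        )
        am = ls_means(df, "y", "g", covariates=["x"])
        for level in ("a", "b"):
            row = am.table.loc[level]
            assert row["ci_low"] < row["mean"] < row["ci_high"]

    def test_unknown_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "b"]})
        with pytest.raises(KeyError):
            ls_means(df, "y", "h")


class TestPartialR:
    def test_zero_t_gives_zero(self):
        rng = np.random.default_rng(7)
        n = 50
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        # orthogonalize y against x exactly so beta == 0
        X = np.column_stack([np.ones(n), x])
        fit0 = fit_ols(X, y)
        resid = y - X @ fit0.params
        fit = fit_ols(pd.DataFrame(X, columns=["intercept", "x"]), resid)
        assert partial_r(fit, "x") == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_conversion(self):
        # t=2, df=98 -> r = sqrt(4/102)
        assert np.sqrt(4 / 102) == pytest.approx(0.19802950, rel=1e-6)
        rng = np.random.default_rng(12)
        n = 100
        x = rng.normal(size=n)
        y = 0.2 * x + rng.normal(size=n)
        fit = fit_ols(pd.DataFrame({"intercept": 1.0, "x": x}), y)
        t = fit["x"]["t"]
        expected = np.sign(t) * np.sqrt(t * t / (t * t + fit.df_resid))
        assert partial_r(fit, "x") == pytest.approx(expected, rel=1e-12)

    def test_perfect_relation_approaches_one(self):
        x = np.arange(1.0, 21.0)
        fit = fit_ols(
            pd.DataFrame({"intercept": 1.0, "x": x}), 3.0 * x + 1.0
        )
        assert abs(partial_r(fit, "x")) > 0.999

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(13)
        n = 80
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 0.3 * x + 0.2 * z + rng.normal(size=n)
        df = pd.DataFrame({"intercept": 1.0, "x": x, "z": z})
        r1 = partial_r(fit_ols(df, y), "x")
        df2 = df.assign(x=1000.0 * df["x"])
        r2 = partial_r(fit_ols(df2, y), "x")
        assert r1 == pytest.approx(r2, rel=1e-10)
        df3 = df.assign(x=-df["x"])
        assert partial_r(fit_ols(df3, y), "x") == pytest.approx(-r1, rel=1e-10)


class TestDesign:
    def test_reference_levels(self):
        df = pd.DataFrame(
            {
                "sex": ["M", "F", "F"],
                "arm": ["lifestyle", "placebo", "metformin"],
                "ethnicity": ["white", "white", "asian"],
            }
        )
        X = build_design(df, factors=["sex", "arm", "ethnicity"])
        assert "sex[M]" in X.columns and "sex[F]" not in X.columns
        assert {"arm[lifestyle]", "arm[metformin]"} <= set(X.columns)
        assert "arm[placebo]" not in X.columns
        assert "ethnicity[asian]" in X.columns  # white is the modal reference

    def test_interaction_columns(self):
        df = pd.DataFrame(
            {"g": [1.0, 2.0, 0.0], "arm": ["placebo", "lifestyle", "lifestyle"]}
        )
        X = build_design(df, numeric=["g"], factors=["arm"], interactions=[("g", "arm")])
        assert X["g:arm[lifestyle]"].tolist() == [0.0, 2.0, 0.0]
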