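"""F-test machinery and single-factor effect curves."""

import numpy as np
import pandas as pd
import pytest

import svrqsar as q
from svrqsar.interpret import DescriptorF, _stars


class TestFQuantile:
    # printed critical values of the F distribution at 2 (or 1) decimals
    @pytest.mark.parametrize("alpha,df1,df2,expected", [
        (0.05, 7, 10, 3.14), (0.01, 7, 10, 5.2),
        (0.05, 11, 6, 4.03), (0.01, 11, 6, 7.8),
        (0.05, 1, 10, 4.96), (0.01, 1, 10, 10.04),
        (0.05, 1, 6, 5.99), (0.01, 1, 6, 13.74),
    ])
    def test_tabulated_critical_values(self, alpha, df1, df2, expected):
        decimals = len(str(expected).split(".")[1])
        tol = 0.51 * 10 ** (-decimals)
        assert q.f_quantile(alpha, df1, df2) == pytest.approx(expected, abs=tol)

    def test_median_equals_one_for_equal_df(self):
        assert q.f_quantile(0.5, 8, 8) == pytest.approx(1.0, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q.f_quantile(0.05, 0, 10)
        with pytest.raises(ValueError):
            q.f_quantile(1.5, 1, 10)


class TestModelSignificance:
    def test_constant_predictor_gives_zero_f(self, rng):
        y = rng.standard_normal(18)

        class Flat:
            feature_names = [f"d{i}" for i in range(7)]
            fitted_values = np.full(18, y.mean())

        report = q.model_significance(Flat(), y)
        assert report.f_model == 0.0
        assert report.df_model == (7, 10)

    def test_equals_classical_anova_f_for_ols_fitted_values(self, rng):
        import statsmodels.api as sm
        n, p = 30, 4
        X = rng.standard_normal((n, p))
        y = X @ rng.uniform(0.5, 1.5, p) + rng.standard_normal(n)
        ols = sm.OLS(y, sm.add_constant(X)).fit()

        class FromOLS:
            feature_names = [f"d{i}" for i in range(p)]
            fitted_values = ols.fittedvalues

        report = q.model_significance(FromOLS(), y)
        assert report.f_model == pytest.approx(ols.fvalue, abs=1e-8)
        assert report.df_model == (p, n - p - 1)

    def test_df_convention_matches_reported_pairs(self):
        # n=18 training compounds: p=7 -> (7, 10); p=11 -> (11, 6)
        y = np.arange(18, dtype=float)

        class M:
            def __init__(self, p):
                self.feature_names = [f"d{i}" for i in range(p)]
                self.fitted_values = y + 0.1

        assert q.model_significance(M(7), y).df_model == (7, 10)
        assert q.model_significance(M(11), y).df_model == (11, 6)

    def test_perfect_fit_flagged_not_infinite(self):
        y = np.arange(10, dtype=float)

        class Perfect:
            feature_names = ["a", "b"]
            fitted_values = y

        report = q.model_significance(Perfect(), y)
        assert report.perfect_fit is True
        assert report.f_model is None


class TestStars:
    def test_between_critical_values_gets_one_star(self):
        # df (1, 10): 4.96 and 10.04 are the alpha=.05/.01 cutoffs
        assert _stars(5.898, 1, 10) == "*"
        assert _stars(12.210, 1, 10) == "**"
        assert _stars(2.387, 1, 10) == "ns"
        assert _stars(7.0, 1, 10) == "*"


class TestDescriptorImportance:
    def test_duplicate_column_has_near_zero_f(self, rng):
        n = 36
        X = rng.standard_normal((n, 3))
        y = X @ np.array([1.5, 1.2, 1.0]) + 0.1 * rng.standard_normal(n)
        frame = pd.DataFrame(np.column_stack([X, X[:, 0]]),
                             index=[f"m{i}" for i in range(n)],
                             columns=["a", "b", "c", "a_dup"])
        act = q.ActivityTable(pd.DataFrame(
            {"pIC50": y, "split": ["train"] * n},
            index=pd.Index(frame.index, name="compound")))
        data = q.make_modeling_dataset(q.DescriptorMatrix(frame), act)
        report = q.descriptor_importance(data, ["a", "b", "c", "a_dup"], q.SVRConfig())
        f_by_name = {d.name: d.f_value for d in report.per_descriptor}
        # the information in a_dup is fully carried by column a, so its
        # removal barely moves the residual sum of squares: its F must sit
        # below every informative column's and below the 5% critical value
        assert f_by_name["a_dup"] < min(f_by_name["a"], f_by_name["b"], f_by_name["c"])
        assert f_by_name["a_dup"] < q.f_quantile(0.05, 1, report.df_model[1])

    def test_permutation_equivariance(self, small_synthetic):
        data, truth = small_synthetic
        names = data.descriptor_names[:4]
        rep1 = q.descriptor_importance(data, names, q.SVRConfig())
        perm = [names[2], names[0], names[3], names[1]]
        rep2 = q.descriptor_importance(data, perm, q.SVRConfig())
        f1 = {d.name: d.f_value for d in rep1.per_descriptor}
        f2 = {d.name: d.f_value for d in rep2.per_descriptor}
        for nm in names:
            assert f1[nm] == pytest.approx(f2[nm], abs=1e-10)

    def test_importance_table_sorted_descending(self, small_synthetic):
        data, _ = small_synthetic
        report = q.descriptor_importance(data, data.descriptor_names[:4], q.SVRConfig())
        tab = report.importance_table()
        assert list(tab["f_value"]) == sorted(tab["f_value"], reverse=True)


class TestSingleFactorEffect:
    def test_model_ignoring_descriptor_reports_flat(self, small_synthetic):
        data, _ = small_synthetic

        class IgnoresSecond:
            feature_names = data.descriptor_names[:2]

            def predict(self, X):
                return 2.0 * np.asarray(X)[:, 0]

        curve = q.single_factor_effect(IgnoresSecond(), data,
                                       data.descriptor_names[1])
        assert curve.direction == "flat"

    def test_monotone_feature_reports_positive(self, small_synthetic):
        data, truth = small_synthetic
        strongest = max(truth.betas, key=truth.betas.get)
        model = q.fit_svr(data.X_train[truth.informative], data.y_train, q.SVRConfig())
        curve = q.single_factor_effect(model, data.subset(truth.informative), strongest)
        assert curve.direction == "positive"
        assert curve.spearman_rho > 0.5

    def test_grid_strictly_increasing_and_spans_training_range(self, small_synthetic):
        data, truth = small_synthetic
        model = q.fit_svr(data.X_train[truth.informative], data.y_train, q.SVRConfig())
        name = truth.informative[0]
        curve = q.single_factor_effect(model, data.subset(truth.informative), name, g=50)
        assert len(curve.grid) == 50
        assert np.all(np.diff(curve.grid) > 0)
        assert curve.grid[0] == data.X_train[name].min()
        assert curve.grid[-1] == data.X_train[name].max()

    def test_unknown_descriptor_rejected(self, small_synthetic):
        data, truth = small_synthetic
        model = q.fit_svr(data.X_train[truth.informative], data.y_train, q.SVRConfig())
        with pytest.raises(ValueError):
            q.single_factor_effect(model, data, "not_a_descriptor")
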