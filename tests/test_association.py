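import numpy as np
import pandas as pd
import pytest

from citrusect.association import (
    collinearity_filter,
    cross_validate,
    default_forest,
    fit_mlr,
    partial_correlations,
    partial_dependence,
    path_interactions,
    shadow_importance,
)


def _frame(arr, prefix="f"):
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


class TestCollinearityFilter:
    def test_three_pairs_leave_18_of_21(self, rng):
        base = rng.normal(size=(100, 18))
        X = _frame(base)
        for i in range(3):
            X[f"dup{i}"] = X[f"f{i}"] + rng.normal(0, 0.01, 100)
        retained, dropped = collinearity_filter(X, threshold=0.95)
        assert len(retained) == 18
        assert len(dropped) == 3

    def test_threshold_one_keeps_all(self, rng):
        X = _frame(rng.normal(size=(50, 6)))
        retained, dropped = collinearity_filter(X, threshold=1.0)
        assert len(retained) == 6 and dropped == []

    def test_identical_copies_keep_one(self, rng):
        col = rng.normal(size=60)
        X = pd.DataFrame({f"c{i}": col for i in range(4)})
        X["other"] = rng.normal(size=60)
        retained, _ = collinearity_filter(X, threshold=0.95)
        assert sum(c.startswith("c") for c in retained) == 1

    def test_no_residual_pair_above_threshold(self, rng):
        base = rng.normal(size=(80, 10))
        X = _frame(base)
        for i in range(4):
            X[f"d{i}"] = X[f"f{i}"] * 1.001 + rng.normal(0, 0.005, 80)
        retained, _ = collinearity_filter(X, threshold=0.95)
        corr = X[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() < 0.95

    def test_constant_column_warns(self, rng):
        X = _frame(rng.normal(size=(40, 3)))
        X["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            retained, _ = collinearity_filter(X)
        assert "const" in retained

    def test_random_policy_seeded(self, rng):
        X = _frame(rng.normal(size=(50, 4)))
        X["dup"] = X["f0"]
        r1, _ = collinearity_filter(X, policy="random", rng=np.random.default_rng(3))
        r2, _ = collinearity_filter(X, policy="random", rng=np.random.default_rng(3))
        assert r1 == r2


class TestFitMlr:
    def test_noiseless_recovery(self, rng):
        X = _frame(rng.normal(size=(100, 5)))
        y = 2.0 * X["f0"] - 1.0 * X["f1"]
        res = fit_mlr(X, y)
        assert res.loc["f0", "pvalue"] < 1e-20
        assert res.loc["f1", "pvalue"] < 1e-20
        assert res.loc["f0", "coefficient_raw"] == pytest.approx(2.0, abs=1e-8)

    def test_orthogonal_design_matches_simple_regression(self, rng):
        n = 64
        # columns exactly orthogonal to each other and to the intercept
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 4))]))
        Q = Q[:, 1:]
        X = _frame(Q)
        y = rng.normal(size=n)
        multi = fit_mlr(X, y, zscore=False)["coefficient"]
        yc = y - y.mean()
        for j, c in enumerate(X.columns):
            x = Q[:, j] - Q[:, j].mean()
            simple = float(x @ yc / (x @ x))
            assert multi[c] == pytest.approx(simple, abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        X = _frame(rng.normal(size=(30, 3)))
        X["dup"] = X["f0"] * 2.0
        with pytest.raises(ValueError, match="dup"):
            fit_mlr(X, rng.normal(size=30))

    def test_needs_more_samples_than_features(self, rng):
        X = _frame(rng.normal(size=(5, 6)))
        with pytest.raises(ValueError, match="n > p"):
            fit_mlr(X, rng.normal(size=5))

    def test_permutation_null_rate(self, rng):
        """p < 0.05 in about 5% of permuted-response fits (small version)."""
        n, p = 108, 10
        X = _frame(rng.normal(size=(n, p)))
        y = rng.normal(size=n)
        hits = total = 0
        for _ in range(60):
            res = fit_mlr(X, rng.permutation(y))
            hits += int((res["pvalue"] < 0.05).sum())
            total += p
        assert abs(hits / total - 0.05) < 0.035


class TestShadowImportance:
    def test_informative_confirmed_noise_rejected(self, rng):
        X = _frame(rng.normal(size=(60, 10)), prefix="x")
        y = X["x0"].to_numpy() + rng.normal(0, 0.2, 60)
        res = shadow_importance(X, y, rng=np.random.default_rng(1),
                                max_iterations=14, n_estimators=50)
        assert res.decision["x0"] == "confirmed"
        noise_rejected = sum(res.decision[f"x{i}"] == "rejected" for i in range(1, 10))
        assert noise_rejected >= 8

    def test_duplicated_informative_both_confirmed(self, rng):
        X = _frame(rng.normal(size=(80, 6)), prefix="x")
        X["x_dup"] = X["x0"] + rng.normal(0, 0.05, 80)
        y = X["x0"].to_numpy() + rng.normal(0, 0.15, 80)
        res = shadow_importance(X, y, rng=np.random.default_rng(2),
                                max_iterations=12, n_estimators=60)
        assert res.decision["x0"] == "confirmed"
        assert res.decision["x_dup"] == "confirmed"

    def test_constant_response_rejects_all(self, rng):
        X = _frame(rng.normal(size=(30, 4)))
        with pytest.warns(UserWarning, match="constant"):
            res = shadow_importance(X, np.ones(30), rng=rng)
        assert (res.decision == "rejected").all()

    def test_reproducible_under_seed(self, rng):
        X = _frame(rng.normal(size=(40, 5)))
        y = X["f0"].to_numpy() + rng.normal(0, 0.3, 40)
        r1 = shadow_importance(X, y, rng=np.random.default_rng(9),
                               max_iterations=5, n_estimators=30)
        r2 = shadow_importance(X, y, rng=np.random.default_rng(9),
                               max_iterations=5, n_estimators=30)
        pd.testing.assert_series_equal(r1.decision, r2.decision)

    def test_small_n_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= 20"):
            shadow_importance(_frame(rng.normal(size=(10, 3))), rng.normal(size=10))


class TestPartialDependence:
    def test_constant_model_flat(self, rng):
        X = _frame(rng.normal(size=(50, 3)))

        class Const:
            def predict(self, A):
                return np.full(len(A), 3.5)

        pd_curve = partial_dependence(Const(), X, "f1", grid_size=8)
        np.testing.assert_allclose(pd_curve["prediction"], 3.5)

    def test_additive_component_recovered(self, rng):
        n = 400
        X = _frame(rng.uniform(-2, 2, size=(n, 2)))
        y = np.sin(X["f0"].to_numpy()) + 0.5 * X["f1"].to_numpy() ** 2
        forest = default_forest(n_estimators=100, random_state=0).fit(X.to_numpy(), y)
        curve = partial_dependence(forest, X, "f0", grid_size=15)
        target = np.sin(curve["grid"].to_numpy())
        assert np.corrcoef(curve["prediction"], target)[0, 1] >= 0.95

    def test_unknown_feature(self, rng):
        X = _frame(rng.normal(size=(30, 2)))
        with pytest.raises(KeyError, match="nope"):
            partial_dependence(default_forest(10).fit(X, rng.normal(size=30)),
                               X, "nope")


class TestPathInteractions:
    def test_stumps_give_zero(self, rng):
        X = rng.normal(size=(200, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 200)
        forest = default_forest(n_estimators=30, random_state=0, max_depth=1)
        forest.fit(X, y)
        scores = path_interactions(forest)
        assert (scores.to_numpy() == 0).all()

    def test_multiplicative_scores_higher_than_additive(self, rng):
        n = 300
        X = rng.uniform(-1, 1, size=(n, 4))
        noise = rng.normal(0, 0.1, n)
        y_mult = X[:, 0] * X[:, 1] + noise
        y_add = 0.5 * X[:, 0] + 0.5 * X[:, 1] + noise
        f_mult = default_forest(50, random_state=1, max_depth=4).fit(X, y_mult)
        f_add = default_forest(50, random_state=1, max_depth=4).fit(X, y_add)
        s_mult = path_interactions(f_mult, min_leaf_fraction=0.02)
        s_add = path_interactions(f_add, min_leaf_fraction=0.02)
        assert s_mult.iloc[0, 1] > s_add.iloc[0, 1]

    def test_scores_in_unit_interval(self, rng):
        X = rng.normal(size=(100, 3))
        y = X[:, 0] * X[:, 1] + rng.normal(0, 0.2, 100)
        forest = default_forest(20, random_state=2, max_depth=5).fit(X, y)
        s = path_interactions(forest).to_numpy()
        assert (s >= 0).all() and (s <= 1.0 + 1e-12).all()


class TestCrossValidate:
    def test_linear_signal_high_r(self, rng):
        n = 200
        X = _frame(rng.normal(size=(n, 5)))
        beta = np.array([1.0, -2.0, 0.5, 0.0, 0.0])
        y = X.to_numpy() @ beta + rng.normal(0, 0.1, n)
        from sklearn.linear_model import LinearRegression
        models = {"MLR": LinearRegression(), "RF": default_forest(100, random_state=0)}
        cv = cross_validate(X, y, rng=np.random.default_rng(0), models=models)
        assert cv["summary"].loc["mean", ("MLR", "r")] >= 0.95

    def test_interaction_favors_rf(self, rng):
        n = 300
        X = _frame(rng.uniform(-1, 1, size=(n, 4)))
        y = X["f0"].to_numpy() * X["f1"].to_numpy() * 4 + rng.normal(0, 0.1, n)
        from sklearn.linear_model import LinearRegression
        models = {"MLR": LinearRegression(), "RF": default_forest(150, random_state=1)}
        cv = cross_validate(X, y, rng=np.random.default_rng(1), models=models)
        assert cv["summary"].loc["mean", ("RF", "r")] > cv["summary"].loc["mean", ("MLR", "r")]
        assert "pvalue" in cv["comparison"]["r"]

    def test_deterministic_under_seed(self, rng):
        X = _frame(rng.normal(size=(60, 3)))
        y = X["f0"].to_numpy() + rng.normal(0, 0.5, 60)
        from sklearn.linear_model import LinearRegression
        models = {"MLR": LinearRegression(), "RF": default_forest(50, random_state=2)}
        a = cross_validate(X, y, rng=np.random.default_rng(5), models=models)
        b = cross_validate(X, y, rng=np.random.default_rng(5), models=models)
        pd.testing.assert_frame_equal(a["per_repeat"], b["per_repeat"])

    def test_too_few_samples(self, rng):
        X = _frame(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="folds"):
            cross_validate(X, rng.normal(size=5), folds=10)


class TestPartialCorrelations:
    def test_two_variables_equal_pearson(self, rng):
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(0, 1, 300)
        df = pd.DataFrame({"x": x, "y": y})
        res = partial_correlations(df)
        pearson = np.corrcoef(x, y)[0, 1]
        assert res.partial.loc["x", "y"] == pytest.approx(pearson, abs=1e-12)

    def test_chain_conditional_independence(self):
        rng = np.random.default_rng(12)
        n = 10000
        x = rng.normal(size=n)
        z = 0.9 * x + rng.normal(0, 0.4, n)
        y = 0.9 * z + rng.normal(0, 0.4, n)
        res = partial_correlations(pd.DataFrame({"x": x, "y": y, "z": z}))
        assert abs(res.partial.loc["x", "y"]) < 0.05
        assert res.apparent.loc["x", "y"] > 0.5

    def test_regression_residual_oracle(self, rng):
        for trial in range(50):
            df = pd.DataFrame(rng.normal(size=(80, 6)),
                              columns=list("abcdef"))
            # add some correlation structure
            df["b"] += 0.5 * df["a"]
            df["c"] += 0.3 * df["b"]
            res = partial_correlations(df)
            Z = df[["c", "d", "e", "f"]].to_numpy()
            Z1 = np.column_stack([np.ones(len(df)), Z])
            ra = df["a"].to_numpy() - Z1 @ np.linalg.lstsq(Z1, df["a"], rcond=None)[0]
            rb = df["b"].to_numpy() - Z1 @ np.linalg.lstsq(Z1, df["b"], rcond=None)[0]
            oracle = np.corrcoef(ra, rb)[0, 1]
            assert res.partial.loc["a", "b"] == pytest.approx(oracle, abs=1e-10)

    def test_symmetry_and_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("wxyz"))
        res = partial_correlations(df)
        np.testing.assert_allclose(res.partial, res.partial.T)
        np.testing.assert_allclose(np.diag(res.partial), 1.0)
        assert ((res.partial.to_numpy() >= -1) & (res.partial.to_numpy() <= 1)).all()

    def test_singular_matrix_advises_filter(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        with pytest.raises(ValueError, match="collinearity_filter"):
            partial_correlations(df)

    def test_needs_enough_samples(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="n > p"):
            partial_correlations(df)


class TestSyntheticDirectionality:
    def test_color_partial_correlation_shrinks(self):
        """Colors tied to degradation via the shared latent lose most of
        their apparent association once the structural features are
        controlled, while the direct driver keeps its correlation."""
        from citrusect.synthetic import default_trait_models, generate_traits, sample_population

        ds = sample_population(150, 1, 1, rng=np.random.default_rng(21), render=False)
        traits = generate_traits(ds.table, default_trait_models()[0],
                                 rng=np.random.default_rng(22))
        df = ds.table[["DegCenter area", "DegAlbedo area", "Whole area",
                       "Flavedo Lab (a)", "Seed area"]].copy()
        df["Peeling"] = traits["continuous"].to_numpy()
        res = partial_correlations(df)
        # direct driver stays significantly negative
        assert res.partial.loc["DegCenter area", "Peeling"] < -0.3
        assert res.partial_pvalues.loc["DegCenter area", "Peeling"] < 0.01
        # color has apparent correlation via the latent, small partial one
        app = abs(res.apparent.loc["Flavedo Lab (a)", "Peeling"])
        par = abs(res.partial.loc["Flavedo Lab (a)", "Peeling"])
        assert par < app
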