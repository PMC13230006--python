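import numpy as np
import pandas as pd
import pytest

from retention_grammar import modeling as md


class TestClassWeights:
    def test_minority_gets_size_ratio(self):
        y = np.array([0] * 100 + [1] * 10)
        assert md.class_weights(y) == {0: 1.0, 1: 10.0}

    def test_balanced_classes_weight_one(self):
        y = np.array([0] * 50 + [1] * 50)
        assert md.class_weights(y) == {0: 1.0, 1: 1.0}

    def test_published_catalog_ratio(self):
        y = np.array([0] * 144241 + [1] * 628)
        assert md.class_weights(y)[1] == pytest.approx(144241 / 628)
        assert md.class_weights(y)[1] == pytest.approx(229.68, abs=0.01)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            md.class_weights(np.zeros(10))


class TestTransformImportance:
    def test_zero_raw_maps_to_zero(self):
        assert md.transform_importance(np.zeros(3), np.ones(3)) == pytest.approx([0, 0, 0])

    def test_raw_equal_to_two_sigma(self):
        t = md.transform_importance(np.array([2.0]), np.array([1.0]))
        assert t[0] == pytest.approx(np.arcsinh(1.0)) == pytest.approx(0.8814, abs=1e-4)

    def test_negative_raw_defined_and_negative(self):
        t = md.transform_importance(np.array([-0.3]), np.array([0.1]))
        assert t[0] < 0 and np.isfinite(t[0])

    def test_zero_sigma_floored_not_infinite(self):
        t = md.transform_importance(np.array([0.5]), np.array([0.0]))
        assert np.isfinite(t[0]) and t[0] > 10  # huge but finite


def make_xy(n=300, p=6, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.2).astype(int)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)])
    if informative:
        X["f0"] = y.astype(float)  # perfectly separating column
    return X, pd.Series(y)


class TestCvRandomForest:
    def test_perfectly_separable_gives_auc_one(self):
        X, y = make_xy()
        rep = md.cv_random_forest(X, y, trees=50, seed=1, compute_importance=False)
        assert rep.mean_auc == pytest.approx(1.0)

    def test_permuted_labels_give_chance_auc(self):
        X, y = make_xy(n=600, informative=False, seed=2)
        rep = md.cv_random_forest(X, y, trees=100, seed=2, compute_importance=False)
        assert rep.mean_auc == pytest.approx(0.5, abs=0.08)

    def test_too_few_minority_samples_rejected(self):
        X, y = make_xy(n=40)
        y[:] = 0
        y.iloc[:3] = 1
        with pytest.raises(ValueError, match="minority"):
            md.cv_random_forest(X, y, trees=10, folds=5)

    def test_importance_table_covers_every_column(self):
        X, y = make_xy()
        rep = md.cv_random_forest(X, y, trees=50, seed=0, importance_repeats=2)
        assert set(rep.importance.index) == set(X.columns)
        assert rep.top_features(1) == ["f0"]

    def test_reports_reproducible_under_seed(self):
        X, y = make_xy(seed=5)
        a = md.cv_random_forest(X, y, trees=30, seed=9, compute_importance=False)
        b = md.cv_random_forest(X, y, trees=30, seed=9, compute_importance=False)
        assert a.fold_aucs == b.fold_aucs


class TestLassoSelect:
    def test_perfect_predictor_ranked_first(self):
        X, y = make_xy(n=400, seed=3)
        sel = md.lasso_select(X, y, seed=0, cv=5)
        assert sel.index[0] == "f0"

    def test_duplicate_columns_redundancy(self):
        """With an exactly duplicated informative column the L1 model
        keeps the signal (a duplicate ranks first) while the noise
        column never outranks it; the split of weight between exact
        twins is solver-dependent and not asserted."""
        rng = np.random.default_rng(4)
        n = 400
        y = pd.Series((rng.random(n) < 0.3).astype(int))
        base = y + rng.normal(scale=0.3, size=n)
        X = pd.DataFrame({"dup1": base, "dup2": base, "noise": rng.normal(size=n)})
        sel = md.lasso_select(X, y, seed=0, cv=5)
        assert sel.index[0] in ("dup1", "dup2")
        if "noise" in sel.index:
            assert sel.loc["noise", "coef"] ** 2 < min(
                sel.loc[d, "coef"] ** 2 for d in ("dup1", "dup2") if d in sel.index
            )

    def test_pure_noise_selects_little(self):
        rng = np.random.default_rng(6)
        y = pd.Series((rng.random(300) < 0.3).astype(int))
        X = pd.DataFrame(rng.normal(size=(300, 10)))
        X.columns = [f"n{i}" for i in range(10)]
        sel = md.lasso_select(X, y, seed=1, cv=5)
        assert len(sel) <= 10  # returns a (possibly empty) ranked frame


class TestMahalanobisMatch:
    def lengths(self, n_cases=3, n_ctrl=100, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(loc=100, scale=10, size=(n_cases + n_ctrl, 3)),
            columns=["len_up", "len_intron", "len_down"],
        )
        y = np.array([1] * n_cases + [0] * n_ctrl)
        return X, y

    def test_twenty_to_one_ratio_counts(self):
        X, y = self.lengths()
        res = md.mahalanobis_match(X, y, ratio=20)
        assert len(res.index) == 3 + 60
        assert (res.clusters.value_counts() == 21).all()

    def test_identity_covariance_equals_euclidean_nearest(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        # whiten: independent unit-variance columns, so Mahalanobis ~ Euclidean
        y = np.array([1] + [0] * 29)
        res = md.mahalanobis_match(X, y, ratio=1)
        d = np.linalg.norm(
            (X.iloc[1:].to_numpy() - X.iloc[0].to_numpy())
            / X.to_numpy().std(axis=0, ddof=1),
            axis=1,
        )
        assert res.index[-1] == X.index[1:][np.argmin(d)]

    def test_identical_control_chosen_at_distance_zero(self):
        X, y = self.lengths(n_cases=1, n_ctrl=50, seed=2)
        X.iloc[10] = X.iloc[0]  # control identical to the case
        res = md.mahalanobis_match(X, y, ratio=1)
        assert X.index[10] in res.index

    def test_insufficient_controls_reports_achievable_ratio(self):
        X, y = self.lengths(n_cases=10, n_ctrl=50)
        with pytest.raises(ValueError, match="achievable ratio 5"):
            md.mahalanobis_match(X, y, ratio=20)


class TestScreeAuc:
    def test_full_width_reproduces_full_model(self):
        X, y = make_xy(n=250, seed=7)
        full = md.cv_random_forest(X, y, trees=50, seed=3, compute_importance=False)
        tab = md.scree_auc(X, y, list(X.columns), ks=[X.shape[1]], seed=3, trees=50)
        assert tab.loc[X.shape[1], "mean_auc"] == pytest.approx(full.mean_auc, abs=0.05)

    def test_single_perfect_feature_reaches_auc_one(self):
        X, y = make_xy(n=250, seed=8)
        tab = md.scree_auc(X, y, ["f0"], ks=[1], seed=0, trees=50)
        assert tab.loc[1, "mean_auc"] == pytest.approx(1.0)

    def test_k_beyond_width_rejected(self):
        X, y = make_xy()
        with pytest.raises(ValueError):
            md.scree_auc(X, y, list(X.columns), ks=[99], trees=10)


class TestCorrelationLandscape:
    def test_duplicated_column_reports_r_one(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=200)})
        X["twin"] = X["a"]
        X["other"] = rng.normal(size=200)
        out = md.correlation_landscape(["a"], X)
        top = out[out["is_max"]].iloc[0]
        assert top["partner"] == "twin" and top["r"] == pytest.approx(1.0)

    def test_independent_columns_stay_below_floor(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(1000, 5)), columns=list("abcde"))
        out = md.correlation_landscape(["a"], X, floor=0.8)
        assert not (out[~out["is_max"]]["r"].abs() >= 0.8).any()

    def test_monotone_nonlinearity_spearman_exceeds_pearson(self):
        x = np.linspace(0.1, 4, 300)
        X = pd.DataFrame({"x": x, "xsq": np.exp(3 * x)})
        sp = md.correlation_landscape(["x"], X, method="spearman")
        pe = md.correlation_landscape(["x"], X, method="pearson")
        r_sp = sp[sp["is_max"]]["r"].iloc[0]
        r_pe = pe[pe["is_max"]]["r"].iloc[0]
        assert r_sp == pytest.approx(1.0) and r_sp > r_pe

    def test_constant_column_skipped(self):
        X = pd.DataFrame({"a": np.arange(50.0), "const": np.ones(50)})
        out = md.correlation_landscape(["a"], X)
        assert "const" not in set(out["partner"])


class TestRunVariant:
    def test_unknown_variant_lists_valid_names(self, tiny_features):
        with pytest.raises(ValueError, match="complete"):
            md.run_variant(tiny_features, "bogus")

    def test_rbp_only_uses_exactly_wavelet_columns(self, tiny_features):
        rep = md.run_variant(
            tiny_features, "rbp_only", trees=20, compute_importance=False
        )
        assert rep.extra["n_features"] == len(tiny_features.groups["rbp"])

    def test_repeats_only_uses_repeat_columns(self, tiny_features):
        rep = md.run_variant(
            tiny_features, "repeats_only", trees=20, compute_importance=False
        )
        assert rep.extra["n_features"] == len(tiny_features.groups["repeat"])
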