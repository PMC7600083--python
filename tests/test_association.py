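import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from dietbiome.association import (
    alpha_regression,
    association_heatmap_table,
    pcoa,
    permanova,
    procrustes_test,
    residualize,
    rf_diet_association,
    zscore_pca,
)
from dietbiome.simulate import generate_covariates


def _rotation(theta):
    return np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )


class TestZscorePCA:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = zscore_pca(df)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_reconstruction_with_all_components(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)))
        res = zscore_pca(df)
        Z = (df - df.mean()) / df.std(ddof=1)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(rec, Z.to_numpy(), atol=1e-8)

    def test_identity_covariance_equal_shares(self, rng):
        df = pd.DataFrame(rng.normal(size=(5000, 10)))
        res = zscore_pca(df)
        assert np.all(np.abs(res.variance_explained - 0.1) < 0.02)

    def test_variance_fractions(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 5)))
        res = zscore_pca(df)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_loadings_orthonormal(self, rng):
        df = pd.DataFrame(rng.normal(size=(60, 4)))
        L = zscore_pca(df).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        a = zscore_pca(df).loadings
        b = zscore_pca(df.copy()).loadings
        pd.testing.assert_frame_equal(a, b)
        for col in a.columns:
            assert a[col].iloc[a[col].abs().argmax()] > 0

    def test_constant_column_dropped_with_warning(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            res = zscore_pca(df)
        assert res.dropped == ["b"]

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            zscore_pca(pd.DataFrame({"a": [1.0]}))


class TestResidualize:
    def test_independent_y_close_to_centered_y(self):
        cov = generate_covariates(500, seed=1)
        rng = np.random.default_rng(2)
        y = rng.normal(size=500)
        resid = residualize(y, cov)
        assert np.corrcoef(resid, y - y.mean())[0, 1] > 0.95
        assert resid.mean() == pytest.approx(0.0, abs=1e-10)

    def test_pure_city_effect_residuals_zero(self):
        cov = generate_covariates(100, seed=3)
        y = cov["city"].map({c: i * 2.0 for i, c in enumerate(cov["city"].unique())})
        resid = residualize(y.to_numpy(), cov)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_orthogonal_to_design(self):
        from dietbiome.association import _design_matrix

        cov = generate_covariates(120, seed=4)
        rng = np.random.default_rng(5)
        y = rng.normal(size=120)
        resid = residualize(y, cov)
        X = _design_matrix(cov)
        assert np.allclose(X.T @ resid, 0.0, atol=1e-8)


class TestAlphaRegression:
    def test_aliased_diet_variable_rejected(self):
        cov = generate_covariates(80, seed=1)
        rng = np.random.default_rng(0)
        alpha = rng.normal(size=80)
        diet = (cov["sex"] == "male").astype(float)
        with pytest.raises(ValueError, match="aliased"):
            alpha_regression(alpha, diet, cov)

    def test_zero_variance_rejected(self):
        cov = generate_covariates(30, seed=1)
        with pytest.raises(ValueError, match="zero variance"):
            alpha_regression(np.zeros(30), np.ones(30), cov)

    def test_null_type_one_error(self):
        cov = generate_covariates(200, seed=2)
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            alpha = rng.normal(size=200)
            diet = rng.normal(size=200)
            if alpha_regression(alpha, diet, cov)["p"] <= 0.05:
                hits += 1
        assert 0.03 <= hits / n_rep <= 0.07

    def test_power_with_planted_effect(self):
        cov = generate_covariates(441, seed=4)
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            diet = rng.normal(size=441)
            alpha = 0.5 * diet + rng.normal(size=441)  # beta = 0.5 SD
            if alpha_regression(alpha, diet, cov)["p"] <= 0.05:
                hits += 1
        assert hits / n_rep > 0.9


class TestPermanova:
    def _euclid(self, X):
        return pd.DataFrame(squareform(pdist(X)))

    def test_r2_partition_identity(self, rng):
        D = self._euclid(rng.normal(size=(30, 4)))
        labels = ["a"] * 15 + ["b"] * 15
        res = permanova(D, labels, n_perm=49, seed=0)
        assert 0.0 <= res.r2 <= 1.0  # between + within = total by construction

    def test_maximal_separation_min_p(self, rng):
        # two groups far apart in Euclidean space
        X = np.vstack([rng.normal(0, 0.1, (10, 3)), rng.normal(50, 0.1, (10, 3))])
        D = self._euclid(X)
        res = permanova(D, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.r2 > 0.99

    def test_p_floor(self, rng):
        D = self._euclid(rng.normal(size=(20, 3)))
        res = permanova(D, ["a"] * 10 + ["b"] * 10, n_perm=99, seed=2)
        assert res.p_value >= 1 / 100

    def test_asymmetric_matrix_rejected(self):
        D = pd.DataFrame(np.arange(9.0).reshape(3, 3))
        with pytest.raises(ValueError, match="symmetric"):
            permanova(D, ["a", "a", "b"])

    def test_single_level_rejected(self, rng):
        D = self._euclid(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError, match="2 levels"):
            permanova(D, ["a"] * 5)

    def test_permutation_stream_reproducible(self, rng):
        D = self._euclid(rng.normal(size=(20, 3)))
        labels = ["a"] * 10 + ["b"] * 10
        r1 = permanova(D, labels, n_perm=99, seed=7)
        r2 = permanova(D, labels, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value


class TestProcrustes:
    def test_rotation_scaling_invariance(self, rng):
        X = rng.normal(size=(50, 3))
        Y = 4.2 * (X @ _rotation(1.1))
        res = procrustes_test(X, Y, n_perm=99, seed=0)
        assert res.correlation == pytest.approx(1.0, abs=1e-10)
        assert res.m2 == pytest.approx(0.0, abs=1e-10)

    def test_reflection_invariance(self, rng):
        X = rng.normal(size=(40, 3))
        Y = X @ np.diag([-1.0, 1.0, 1.0])
        res = procrustes_test(X, Y, n_perm=9, seed=0)
        assert res.correlation == pytest.approx(1.0, abs=1e-10)

    def test_identity_corr2_plus_m2(self, rng):
        for _ in range(10):
            X = rng.normal(size=(30, 3))
            Y = rng.normal(size=(30, 3))
            res = procrustes_test(X, Y, n_perm=9, seed=1)
            assert res.correlation**2 + res.m2 == pytest.approx(1.0, abs=1e-10)
            assert 0.0 <= res.correlation <= 1.0

    def test_row_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_test(rng.normal(size=(10, 2)), rng.normal(size=(11, 2)))

    def test_seeded_p_reproducible(self, rng):
        X, Y = rng.normal(size=(25, 3)), rng.normal(size=(25, 3))
        assert (
            procrustes_test(X, Y, 199, seed=3).p_value
            == procrustes_test(X, Y, 199, seed=3).p_value
        )


class TestPcoa:
    def test_recovers_euclidean_configuration(self, rng):
        X = rng.normal(size=(20, 3))
        D = pd.DataFrame(squareform(pdist(X)))
        coords = pcoa(D, n_axes=3)
        D2 = squareform(pdist(coords.to_numpy()))
        assert np.allclose(D2, D.to_numpy(), atol=1e-8)


def _planted_rf_data(n, p, k, effect, seed):
    rng = np.random.default_rng(seed)
    X = rng.dirichlet(np.ones(p) * 0.8, size=n)
    driver = rng.normal(size=n)
    # planted OTUs co-vary with the driver
    X[:, :k] *= np.exp(effect * driver[:, None] * 0.5)
    X /= X.sum(axis=1, keepdims=True)
    cols = [f"O{i:03d}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), driver


class TestRandomForest:
    def test_null_oob_r2_small(self):
        r2s = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.dirichlet(np.ones(15), size=80),
                columns=[f"O{i}" for i in range(15)],
            )
            y = rng.normal(size=80)
            res = rf_diet_association(X, y, n_trees=150, seed=seed, rfe=False)
            r2s.append(res.explained_variance)
        assert np.mean(r2s) <= 0.05

    def test_planted_recovery_and_signs(self):
        X, y = _planted_rf_data(n=300, p=30, k=5, effect=1.0, seed=1)
        res = rf_diet_association(X, y, n_trees=400, seed=1, rfe=False)
        top10 = res.full_importance.sort_values(ascending=False).index[:10]
        planted = [f"O{i:03d}" for i in range(5)]
        assert sum(o in top10 for o in planted) >= 4
        in_sel = [o for o in planted if o in res.spearman_rho.index]
        assert all(res.spearman_rho[o] > 0 for o in in_sel)

    def test_recovery_improves_with_effect_size(self):
        recovered = []
        for effect in [0.0, 0.8, 2.0]:
            X, y = _planted_rf_data(n=200, p=20, k=4, effect=effect, seed=7)
            res = rf_diet_association(X, y, n_trees=200, seed=7, rfe=False)
            top = res.full_importance.sort_values(ascending=False).index[:4]
            recovered.append(sum(f"O{i:03d}" in top for i in range(4)))
        assert recovered[0] <= recovered[1] <= recovered[2]
        assert recovered[2] == 4

    def test_importance_sorted_nonincreasing(self):
        X, y = _planted_rf_data(n=120, p=12, k=3, effect=1.0, seed=3)
        res = rf_diet_association(X, y, n_trees=150, seed=3)
        assert (np.diff(res.importance.to_numpy()) <= 1e-12).all()
        assert res.spearman_rho.abs().max() <= 1.0

    def test_rfe_keeps_best_subset(self):
        X, y = _planted_rf_data(n=150, p=16, k=3, effect=1.5, seed=5)
        res = rf_diet_association(X, y, n_trees=150, seed=5)
        sizes = [s for s, _ in res.rfe_path]
        assert sizes[0] == 16 and sizes[-1] <= 2 * sizes[-2] if len(sizes) > 1 else True
        best_r2 = max(r for _, r in res.rfe_path)
        assert res.explained_variance == pytest.approx(best_r2)

    def test_constant_diet_variable_rejected(self, rng):
        X = pd.DataFrame(rng.dirichlet(np.ones(5), size=60))
        with pytest.raises(ValueError, match="constant"):
            rf_diet_association(X, np.ones(60), n_trees=10)

    def test_deterministic_under_seed(self):
        X, y = _planted_rf_data(n=100, p=10, k=2, effect=1.0, seed=9)
        a = rf_diet_association(X, y, n_trees=100, seed=4)
        b = rf_diet_association(X, y, n_trees=100, seed=4)
        assert a.selected_otus == b.selected_otus
        assert a.explained_variance == b.explained_variance


class TestHeatmapTable:
    def _result(self, X, y, name, seed=0):
        return rf_diet_association(X, y, n_trees=80, seed=seed, diet_variable=name)

    def test_single_variable_rows(self):
        X, y = _planted_rf_data(n=80, p=6, k=2, effect=1.5, seed=2)
        res = self._result(X, y, "fiber")
        diet = pd.DataFrame({"fiber": y})
        table = association_heatmap_table([res], X, diet)
        assert set(table["diet_variable"]) == {"fiber"}
        assert len(table) == len(res.selected_otus)

    def test_unselected_otu_absent(self):
        X, y = _planted_rf_data(n=80, p=8, k=2, effect=1.5, seed=3)
        res = self._result(X, y, "fiber")
        diet = pd.DataFrame({"fiber": y})
        table = association_heatmap_table([res], X, diet)
        assert set(table["otu_id"]) == set(res.selected_otus)

    def test_rho_filled_for_all_pairs_and_stable(self):
        X, y1 = _planted_rf_data(n=90, p=8, k=2, effect=1.5, seed=4)
        y2 = np.random.default_rng(5).normal(size=90)
        r1 = self._result(X, y1, "fiber")
        r2 = self._result(X, y2, "fat", seed=1)
        diet = pd.DataFrame({"fiber": y1, "fat": y2})
        t1 = association_heatmap_table([r1, r2], X, diet)
        t2 = association_heatmap_table([r1, r2], X, diet)
        pd.testing.assert_frame_equal(t1, t2)
        assert not t1["rho"].isna().any()
        union = set(r1.selected_otus) | set(r2.selected_otus)
        assert len(t1) == 2 * len(union)

    def test_empty_results(self):
        table = association_heatmap_table([], pd.DataFrame(), pd.DataFrame())
        assert table.empty
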