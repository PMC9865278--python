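"""OPLS-DA/VIP, Spearman with exact permutation p, RF node-purity importance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eoscreen import chemometrics as chem
from eoscreen.errors import DegenerateDesignError, DegenerateResponseWarning


class TestSpearman:
    def test_monotone_extremes(self):
        rho, _ = chem.spearman_pair([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = chem.spearman_pair([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_closed_form_adjacent_swap(self):
        # n=6 untied ranks, one adjacent swap: rho = 1 - 6*2/(6*35) = 0.9429
        rho, _ = chem.spearman_pair([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 6, 5])
        assert rho == pytest.approx(1 - 12 / 210)

    def test_exact_p_matches_brute_enumeration(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 2.0])
        y = np.array([2.0, 0.5, 3.5, 1.0, 4.0, 2.5])
        _, p = chem.spearman_pair(x, y)
        obs = abs(stats.spearmanr(x, y).statistic)
        count = sum(
            abs(stats.spearmanr(x, np.asarray(perm).astype(float)).statistic)
            >= obs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert p == pytest.approx(count / 720)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        rho1, p1 = chem.spearman_pair(x, y)
        rho2, p2 = chem.spearman_pair(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_column_undefined(self):
        rho, p = chem.spearman_pair([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_matrix_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc"))
        res = chem.spearman_matrix(x)
        assert np.allclose(res.rho, res.rho.T, equal_nan=True)
        assert np.allclose(np.diag(res.rho), 1.0)

    def test_stars_convention(self):
        assert chem.significance_stars(0.0005) == "***"
        assert chem.significance_stars(0.005) == "**"
        assert chem.significance_stars(0.03) == "*"
        assert chem.significance_stars(0.2) == ""

    def test_insufficient_samples(self):
        with pytest.raises(DegenerateDesignError):
            chem.spearman_pair([1.0, 2.0], [2.0, 1.0])


def two_class_data(n_per=20, p=5, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per, p))
    X[:n_per, 0] += delta
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return pd.DataFrame(X, columns=[f"v{i}" for i in range(p)]), y


class TestOplsDa:
    def test_planted_variable_dominates_loading(self):
        X, y = two_class_data(delta=4.0, seed=2)
        model = chem.fit_opls_da(X, y, scaling="uv")
        w = np.abs(model.weights_[:, 0])
        assert np.argmax(w) == 0

    def test_null_structure_low_r2y(self):
        X, y = two_class_data(n_per=50, delta=0.0, seed=3)
        model = chem.fit_opls_da(X, y, cross_validate=False)
        assert model.r2y_ < 0.2

    def test_duplicated_samples_identical_scores(self):
        X, y = two_class_data(n_per=6, delta=3.0, seed=4)
        X2 = pd.concat([X, X.iloc[[0]]], ignore_index=True)
        y2 = np.append(y, y[0])
        model = chem.fit_opls_da(X2, y2, cross_validate=False)
        assert np.allclose(model.scores_[0], model.scores_[-1], atol=1e-8)

    def test_orthogonality_of_score_blocks(self, rosemary_replicates):
        x, labels = rosemary_replicates.replicate_matrix()
        model = chem.fit_opls_da(
            x.reset_index(drop=True), labels.to_numpy(), cross_validate=False
        )
        cross = model.scores_.T @ model.orth_scores_
        assert np.all(np.abs(cross) < 1e-8)

    def test_limit_case_equals_plain_pls(self):
        # n_orth=0, mean-centering only: first predictive scores match a
        # two-block PLS regression (independent implementation) up to sign
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_data(n_per=15, delta=2.0, seed=5)
        model = chem.fit_opls_da(
            X, y, n_orth=0, scaling="none", n_predictive=1, cross_validate=False
        )
        Y = (y == "a").astype(float)
        pls = PLSRegression(n_components=1, scale=False).fit(X, Y)
        t_mine = model.scores_[:, 0]
        t_ref = pls.x_scores_[:, 0]
        corr = np.corrcoef(t_mine, t_ref)[0, 1]
        assert abs(corr) > 1 - 1e-10

    def test_single_class_rejected(self):
        X, _ = two_class_data()
        with pytest.raises(DegenerateDesignError):
            chem.fit_opls_da(X, np.repeat("a", len(X)))

    def test_zero_variance_variable_dropped(self):
        X, y = two_class_data(seed=6)
        X["dead"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            model = chem.fit_opls_da(X, y, cross_validate=False)
        assert "dead" not in model.feature_names_


class TestVip:
    @pytest.mark.parametrize("scaling", ["pareto", "uv", "none"])
    def test_normalization_sum_of_squares(self, scaling, rosemary_replicates):
        x, labels = rosemary_replicates.replicate_matrix()
        model = chem.fit_opls_da(
            x.reset_index(drop=True), labels.to_numpy(), scaling=scaling,
            cross_validate=False,
        )
        vip = chem.vip_scores(model)
        assert (vip**2).sum() == pytest.approx(len(vip), abs=1e-8)

    def test_single_informative_variable(self):
        X, y = two_class_data(delta=5.0, seed=7)
        model = chem.fit_opls_da(X, y, scaling="uv", cross_validate=False)
        vip = chem.vip_scores(model)
        assert vip["v0"] > 1.0
        assert (vip.drop("v0") < 1.0).all()

    def test_exchangeable_variables_all_unit(self):
        # four identical copies of the class indicator: symmetry forces VIP=1
        y = np.array(["a"] * 5 + ["b"] * 5)
        base = (y == "a").astype(float) + np.linspace(0, 0.1, 10)
        X = pd.DataFrame({f"v{i}": base for i in range(4)})
        model = chem.fit_opls_da(X, y, scaling="none", n_orth=0, cross_validate=False)
        vip = chem.vip_scores(model)
        assert np.allclose(vip, 1.0, atol=1e-8)

    def test_main_components_top_five_on_panel(self, rosemary_replicates):
        x, labels = rosemary_replicates.replicate_matrix()
        model = chem.fit_opls_da(
            x.reset_index(drop=True), labels.to_numpy(), cross_validate=False
        )
        vip = chem.vip_scores(model)
        top5 = set(vip.sort_values(ascending=False).index[:5])
        assert top5 == {"Camphor", "Verbenone", "α-Pinene", "1,8-Cineole", "Bornyl acetate"}

    def test_screen_components(self):
        vip = pd.Series({"a": 1.7, "b": 0.4, "c": 1.2})
        assert chem.screen_components(vip, 1.0) == ["a", "c"]
        assert chem.screen_components(vip, 0.0) == ["a", "c", "b"]
        assert chem.screen_components(vip, 5.0) == []
        with pytest.raises(ValueError):
            chem.screen_components(vip, -1.0)


class TestRandomForestImportance:
    @staticmethod
    def planted(seed, n=60, p=11, snr=5.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"v{i}" for i in range(p)])
        signal = X["v0"].to_numpy()
        y = signal + rng.normal(0, signal.std() / snr, n)
        return X, y

    def test_planted_feature_recovered(self):
        X, y = self.planted(seed=0)
        imp = chem.rf_regression_importance(X, y, n_trees=300, seed=0)
        assert imp.importances.idxmax() == "v0"
        assert (imp.importances >= 0).all()

    def test_bit_identical_under_seed(self):
        X, y = self.planted(seed=1)
        a = chem.rf_regression_importance(X, y, n_trees=100, seed=3)
        b = chem.rf_regression_importance(X, y, n_trees=100, seed=3)
        assert (a.importances == b.importances).all()

    def test_constant_response_near_zero(self):
        X, _ = self.planted(seed=2)
        with pytest.warns(DegenerateResponseWarning):
            imp = chem.rf_regression_importance(X, np.ones(len(X)), n_trees=50, seed=0)
        assert imp.importances.abs().max() == pytest.approx(0.0, abs=1e-9)

    def test_ranking_stable_across_seeds(self):
        X, y = self.planted(seed=4)
        for seed in range(10):
            imp = chem.rf_regression_importance(X, y, n_trees=100, seed=seed)
            assert imp.importances.idxmax() == "v0"

    def test_too_few_samples(self):
        X = pd.DataFrame(np.eye(3))
        with pytest.raises(DegenerateDesignError):
            chem.rf_regression_importance(X, [1.0, 2.0, 3.0])
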