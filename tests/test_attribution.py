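"""Shapley attribution: axioms, the enumeration oracle, and tree equivalence."""

import numpy as np
import pytest

from specswarm import (
    AttributionMatrix,
    TreeShapExplainer,
    exact_shapley,
    fit_fixed_model,
    rank_features,
    tree_shapley,
)


@pytest.fixture(scope="module")
def small_ensemble(request):
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 6)).astype(np.float32)
    y = 2 * X[:, 0] + np.sin(X[:, 2]) - X[:, 4] ** 2 + rng.normal(0, 0.05, 40)
    model = fit_fixed_model(X, y, {"n_estimators": 3, "max_depth": 2})
    return model, X


class TestExactShapley:
    def test_hand_computed_three_player_game(self):
        # f = 4 z0 z1 + 3 z0 with x = ones, background = zeros:
        # the unanimity term splits 2/2 between players 0 and 1 and the
        # singleton term goes wholly to player 0 -> phi = (5, 2, 0)
        def f(Z):
            return 4 * Z[:, 0] * Z[:, 1] + 3 * Z[:, 0]

        phi = exact_shapley(f, np.ones(3), np.zeros((1, 3)))
        assert np.allclose(phi, [5.0, 2.0, 0.0])

    def test_additive_model_recovers_marginal_effects(self, rng):
        bg = rng.normal(size=(25, 3))

        def f(Z):
            return Z[:, 0] ** 2 + 3 * Z[:, 1] - np.abs(Z[:, 2])

        x = np.array([1.5, -0.5, 2.0])
        phi = exact_shapley(f, x, bg)
        expected = [
            x[0] ** 2 - np.mean(bg[:, 0] ** 2),
            3 * x[1] - np.mean(3 * bg[:, 1]),
            -abs(x[2]) - np.mean(-np.abs(bg[:, 2])),
        ]
        assert np.allclose(phi, expected, atol=1e-12)

    def test_symmetry_axiom(self):
        def f(Z):
            return Z[:, 0] * Z[:, 1]

        phi = exact_shapley(f, np.array([2.0, 2.0]), np.zeros((1, 2)))
        assert phi[0] == pytest.approx(phi[1])

    def test_refuses_large_p(self):
        with pytest.raises(ValueError, match="12"):
            exact_shapley(lambda Z: Z.sum(1), np.ones(13), np.ones((2, 13)))


class TestTreeShapley:
    def test_constant_model_all_zero(self, rng):
        X = rng.normal(size=(20, 4)).astype(np.float32)
        model = fit_fixed_model(X, np.full(20, 7.0), {"n_estimators": 2})
        am = tree_shapley(model, X[:5], X)
        assert np.allclose(am.values, 0.0)
        assert am.base_value == pytest.approx(7.0, abs=1e-6)

    def test_stump_attributes_only_split_feature(self, rng):
        X = rng.normal(size=(60, 4)).astype(np.float32)
        y = np.where(X[:, 1] > 0, 3.0, -3.0)
        model = fit_fixed_model(X, y, {"n_estimators": 1, "max_depth": 1,
                                       "learning_rate": 1.0})
        expl = TreeShapExplainer(model, X)
        am = expl.attribute(X[:10])
        others = [0, 2, 3]
        assert np.allclose(am.values[:, others], 0.0)
        assert np.allclose(
            am.values[:, 1], am.predictions - am.base_value, atol=1e-10
        )

    def test_matches_enumeration_oracle(self, small_ensemble):
        model, X = small_ensemble
        bg = X[:20]
        expl = TreeShapExplainer(model, bg)
        am = expl.attribute(X[20:28])
        for i in range(8):
            phi = exact_shapley(expl.predict, X[20 + i], bg)
            assert np.max(np.abs(phi - am.values[i])) <= 1e-6

    def test_local_accuracy(self, small_ensemble):
        model, X = small_ensemble
        am = tree_shapley(model, X[25:], X[:25])
        assert am.local_accuracy_error() <= 1e-6

    def test_explainer_prediction_matches_booster(self, small_ensemble):
        model, X = small_ensemble
        expl = TreeShapExplainer(model, X[:10])
        assert np.max(np.abs(expl.predict(X) - model.predict(X))) <= 1e-4

    def test_dummy_feature_gets_zero(self, rng):
        X = rng.normal(size=(50, 5)).astype(np.float32)
        y = np.where(X[:, 0] > 0, 2.0, -1.0)
        model = fit_fixed_model(X, y, {"n_estimators": 5, "max_depth": 2})
        expl = TreeShapExplainer(model, X)
        used = set()
        for leaf in expl._leaves:
            used.update(leaf.features.tolist())
        unused = sorted(set(range(5)) - used)
        assert unused, "expected at least one feature unused by the ensemble"
        am = expl.attribute(X[:10])
        assert np.allclose(am.values[:, unused], 0.0)

    def test_non_tree_model_rejected(self, rng):
        class Linear:
            def predict(self, X):
                return X.sum(axis=1)

        with pytest.raises(TypeError, match="tree"):
            tree_shapley(Linear(), rng.normal(size=(3, 2)),
                         rng.normal(size=(3, 2)))

    def test_background_subsampling_deterministic(self, small_ensemble):
        model, X = small_ensemble
        a = tree_shapley(model, X[:4], X, max_background=10, seed=3)
        b = tree_shapley(model, X[:4], X, max_background=10, seed=3)
        assert np.array_equal(a.values, b.values)


class TestRankFeatures:
    def _am(self, values, labels):
        values = np.asarray(values, dtype=float)
        return AttributionMatrix(
            values=values,
            base_value=0.0,
            feature_labels=np.asarray(labels, dtype=float),
            predictions=values.sum(axis=1),
        )

    def test_all_zero_ties_by_ascending_wavelength(self):
        am = self._am(np.zeros((3, 4)), [800, 400, 600, 500])
        ranked = rank_features(am, 4)
        assert [w for w, _ in ranked] == [400, 500, 600, 800]

    def test_dominant_column_first(self):
        am = self._am([[0.1, 5.0, -0.2], [0.05, -4.0, 0.1]], [400, 404, 408])
        ranked = rank_features(am, 2)
        assert ranked[0][0] == 404
        assert ranked[0][1] == pytest.approx(4.5)

    def test_top_k_bounded(self):
        am = self._am(np.zeros((2, 3)), [1, 2, 3])
        with pytest.raises(ValueError, match="top_k"):
            rank_features(am, 4)
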