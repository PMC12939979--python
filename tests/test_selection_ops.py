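"""Unit behaviour of the metaheuristic operators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import kurtosis

from specswarm import (
    CVFitness,
    SelectionMask,
    SelectorConfig,
    binarize,
    classify_population,
    crossover,
    inertia,
    levy_sigma,
    levy_step,
    logistic_init,
    polynomial_mutation,
    pso_update,
)


class TestLogisticInit:
    def test_single_map_step(self):
        assert 4 * 0.3 * 0.7 == pytest.approx(0.84)

    def test_values_strictly_inside_unit_interval(self):
        pop = logistic_init(20, 50, r=4.0, rng=0)
        assert pop.shape == (20, 50)
        assert np.all(pop > 0.0) and np.all(pop < 1.0)

    def test_invariant_density_mean(self):
        # the r=4 orbit follows the arcsine law, whose mean is 1/2
        orbit = logistic_init(1, 100_000, r=4.0, rng=1)[0]
        assert 0.3 < orbit.mean() < 0.7

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            logistic_init(2, 4, r=4.5)

    def test_deterministic(self):
        a = logistic_init(5, 10, rng=3)
        b = logistic_init(5, 10, rng=3)
        assert np.array_equal(a, b)


class TestBinarize:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            ([0.9, 0.1, 0.51], [1, 0, 1]),
            ([0.2, 0.4, 0.3], [0, 1, 0]),   # empty-mask rescue
            ([0.5, 0.5, 0.5], [1, 0, 0]),   # strict threshold, rescue to argmax
        ],
    )
    def test_examples(self, pos, expected):
        assert binarize(np.array(pos)).flags.tolist() == [bool(b) for b in expected]

    @given(pos=arrays(float, 15, elements=st.floats(0, 1)))
    def test_never_empty(self, pos):
        assert binarize(pos).n_selected >= 1


class TestInertia:
    def test_boundaries_and_midpoint(self):
        cfg = SelectorConfig(max_iter=100, w_max=0.9, w_min=0.4)
        assert inertia(0, cfg) == pytest.approx(0.9)
        assert inertia(100, cfg) == pytest.approx(0.4)
        assert inertia(50, cfg) == pytest.approx(0.4 + 0.5 * 0.25)

    def test_exponential_mode_boundaries(self):
        cfg = SelectorConfig(max_iter=10, inertia_mode="exp")
        assert inertia(0, cfg) == pytest.approx(cfg.w_max)
        assert inertia(10, cfg) == pytest.approx(cfg.w_min)

    def test_out_of_range_iteration(self):
        with pytest.raises(ValueError):
            inertia(101, SelectorConfig(max_iter=100))


class TestClassifyPopulation:
    def test_half_split(self):
        cfg = SelectorConfig(pop_size=4, max_iter=10,
                             elite_share_start=0.5, elite_share_end=0.5)
        elite, ordinary = classify_population(np.array([3.0, 1.0, 2.0, 4.0]), 5, cfg)
        assert elite.tolist() == [1, 2] and ordinary.tolist() == [0, 3]

    def test_share_at_t0_is_start(self):
        cfg = SelectorConfig(pop_size=10, max_iter=10,
                             elite_share_start=0.5, elite_share_end=0.2)
        elite, _ = classify_population(np.arange(10.0), 0, cfg)
        assert elite.size == math.ceil(0.5 * 10)

    def test_ties_break_to_lowest_index(self):
        cfg = SelectorConfig(pop_size=6, max_iter=10,
                             elite_share_start=0.5, elite_share_end=0.5)
        elite, _ = classify_population(np.zeros(6), 0, cfg)
        assert elite.tolist() == [0, 1, 2]


class TestPsoUpdate:
    def test_fixed_point(self):
        cfg = SelectorConfig()
        rng = np.random.default_rng(0)
        x = np.full(5, 0.4)
        nx, nv = pso_update(x, np.zeros(5), x, x, 0.7, cfg, rng)
        assert np.allclose(nx, x) and np.allclose(nv, 0)

    def test_moves_toward_global_best(self):
        cfg = SelectorConfig(c1=0.0, c2=1.0, v_clamp=10.0)

        class OneRng:
            def random(self, size=None):
                return np.ones(size)

        x = np.array([0.2, 0.8])
        gbest = np.array([0.6, 0.6])
        nx, _ = pso_update(x, np.zeros(2), x, gbest, 0.0, cfg, OneRng())
        assert np.allclose(nx, gbest)

    @given(
        x=arrays(float, 8, elements=st.floats(0, 1)),
        v=arrays(float, 8, elements=st.floats(-2, 2)),
    )
    def test_position_stays_in_unit_box(self, x, v):
        cfg = SelectorConfig()
        nx, nv = pso_update(x, v, x, x, 0.9, cfg, np.random.default_rng(0))
        assert np.all(nx >= 0) and np.all(nx <= 1)
        assert np.all(np.abs(nv) <= cfg.v_clamp + 1e-12)


class TestCrossover:
    def test_identical_parents(self, rng):
        a = rng.random(10)
        ca, cb = crossover(a, a.copy(), 1.0, rng)
        assert np.array_equal(ca, a) and np.array_equal(cb, a)

    def test_disabled_crossover(self, rng):
        a, b = rng.random(10), rng.random(10)
        ca, cb = crossover(a, b, 0.0, rng)
        assert np.array_equal(ca, a) and np.array_equal(cb, b)

    def test_coordinatewise_multiset_conserved(self, rng):
        a, b = rng.random(30), rng.random(30)
        ca, cb = crossover(a, b, 1.0, rng)
        assert np.allclose(np.sort(np.c_[ca, cb]), np.sort(np.c_[a, b]))


class TestLevy:
    def test_sigma_closed_form_beta_1_5(self):
        # independent evaluation of the Mantegna scale expression
        beta = 1.5
        expected = (
            math.gamma(2.5) * math.sin(0.75 * math.pi)
            / (math.gamma(1.25) * 1.5 * 2**0.25)
        ) ** (2 / 3)
        assert expected == pytest.approx(0.696575, abs=1e-5)
        assert levy_sigma(beta) == pytest.approx(expected, rel=1e-12)

    def test_zero_scale(self):
        assert np.allclose(levy_step(50, 1.5, 0.0, np.random.default_rng(0)), 0)

    def test_heavy_tail_kurtosis(self):
        draws = levy_step(100_000, 1.5, 1.0, np.random.default_rng(2))
        assert kurtosis(draws, fisher=True) > 10

    def test_beta_out_of_range(self):
        with pytest.raises(ValueError):
            levy_step(5, 2.5, 1.0, np.random.default_rng(0))


class TestPolynomialMutation:
    def test_no_mutation(self, rng):
        x = rng.random(20)
        assert np.array_equal(
            polynomial_mutation(x, 20.0, 0.0, np.zeros(20), rng), x
        )

    def test_output_in_unit_box(self, rng):
        x = rng.random(200)
        levy = levy_step(200, 1.5, 0.5, rng)
        out = polynomial_mutation(x, 20.0, 1.0, levy, rng)
        assert np.all(out >= 0) and np.all(out <= 1)

    def test_large_eta_shrinks_perturbations(self, rng):
        # the polynomial-mutation quantile scales like |log u| / eta for
        # large distribution index, so eta = 1e6 bounds |delta| by ~1e-3
        x = np.full(10_000, 0.5)
        out = polynomial_mutation(x, 1e6, 1.0, np.zeros(10_000), rng)
        assert np.max(np.abs(out - x)) <= 1e-3


class TestCvFitness:
    def test_constant_target_scores_zero(self, rng):
        X = rng.random((24, 6))
        fit = CVFitness(X, np.full(24, 5.0), folds=3, seed=0,
                        n_estimators=10, max_bin=16)
        assert fit(SelectionMask.full(6)) == pytest.approx(0.0, abs=1e-10)

    def test_memoised_by_bit_pattern(self, rng):
        X = rng.random((24, 6))
        y = rng.random(24)
        fit = CVFitness(X, y, folds=3, seed=0, n_estimators=10, max_bin=16)
        mask = SelectionMask(np.array([1, 0, 1, 0, 1, 0], bool))
        a = fit(mask)
        n_evals = fit.evaluations
        b = fit(SelectionMask(mask.flags.copy()))
        assert a == b and fit.evaluations == n_evals

    def test_empty_mask_rejected(self, rng):
        fit = CVFitness(rng.random((12, 4)), rng.random(12), folds=3, seed=0,
                        n_estimators=5)
        with pytest.raises(ValueError, match="empty"):
            fit(SelectionMask(np.zeros(4, bool)))

    def test_informative_mask_beats_noise_mask(self):
        # y generated from three columns plus mild noise: the generating
        # columns must always out-score pure-noise columns
        g = np.random.default_rng(42)
        X = g.normal(size=(60, 12))
        y = 3 * X[:, 1] + 2 * X[:, 5] - X[:, 9] + g.normal(0, 0.2, 60)
        for seed in range(10):
            fit = CVFitness(X, y, folds=3, seed=seed,
                            n_estimators=20, learning_rate=0.3, max_bin=16)
            f_true = fit(SelectionMask.from_indices([1, 5, 9], 12))
            f_noise = fit(SelectionMask.from_indices([0, 4, 8], 12))
            assert f_true < f_noise

    def test_too_few_samples_per_fold(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            CVFitness(rng.random((5, 3)), rng.random(5), folds=3, seed=0)
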