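"""GRU cell algebra, GA operator contracts and the GA-GRU search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import expotox.gagru as gg


def _zero_params(n_in=2, hidden=3):
    return gg.GRUParams(
        Wr=np.zeros((hidden, n_in)), Ur=np.zeros((hidden, hidden)),
        Wz=np.zeros((hidden, n_in)), Uz=np.zeros((hidden, hidden)),
        U=np.zeros((hidden, n_in)), W=np.zeros((hidden, hidden)),
        bh=np.zeros(hidden))


class TestGRUStep:
    def test_zero_weights_algebra(self):
        """sigma(0) = 0.5 and tanh(0) = 0 force r = z = 0.5, candidate 0,
        and h_t = 0.5 * h_prev."""
        h_prev = np.array([1.0, -2.0, 0.5])
        st_ = gg.gru_step(_zero_params(), np.ones(2), h_prev)
        np.testing.assert_allclose(st_.r, 0.5)
        np.testing.assert_allclose(st_.z, 0.5)
        np.testing.assert_allclose(st_.h_tilde, 0.0)
        np.testing.assert_allclose(st_.h, 0.5 * h_prev)

    def test_update_gate_one_preserves_state(self):
        params = _zero_params()
        params.Wz += 100.0  # huge update-gate drive -> z ~= 1
        h_prev = np.array([0.3, -0.7, 1.2])
        st_ = gg.gru_step(params, np.ones(2), h_prev)
        np.testing.assert_allclose(st_.h, h_prev, atol=1e-8)

    def test_gates_in_unit_interval_and_hidden_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            params = gg.GRUParams.init(4, 6, rng)
            x = rng.normal(scale=3.0, size=4)
            h_prev = rng.normal(scale=2.0, size=6)
            st_ = gg.gru_step(params, x, h_prev)
            assert ((st_.r > 0) & (st_.r < 1)).all()
            assert ((st_.z > 0) & (st_.z < 1)).all()
            assert (np.abs(st_.h_tilde) < 1).all()
            bound = np.maximum(np.abs(h_prev), 1.0)
            assert (np.abs(st_.h) <= bound + 1e-12).all()

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            gg.gru_step(_zero_params(), np.array([np.nan, 1.0]), np.zeros(3))


class TestFitness:
    def test_perfect_predictions_zero(self):
        assert gg.fitness([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_direct_substitution(self):
        assert gg.fitness([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_population_total(self):
        assert gg.population_fitness([0.5, 1.5]) == 2.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gg.fitness([], [])


class TestRoulette:
    def test_probabilities_forced_by_formula(self):
        np.testing.assert_allclose(gg.roulette_probabilities([1.0, 3.0]),
                                   [0.75, 0.25])

    def test_equal_fitness_uniform(self):
        np.testing.assert_allclose(gg.roulette_probabilities([2.0] * 4), 0.25)

    def test_scale_invariance(self):
        E = np.array([0.2, 0.5, 1.1])
        np.testing.assert_allclose(gg.roulette_probabilities(E),
                                   gg.roulette_probabilities(10.0 * E))

    def test_empirical_frequencies_match(self):
        """Selection frequencies over 10,000 draws within +-0.02 of P."""
        rng = np.random.default_rng(42)
        E = [1.0, 3.0]
        draws = np.array([gg.roulette_select(E, rng) for _ in range(10_000)])
        freq = np.bincount(draws, minlength=2) / 10_000
        np.testing.assert_allclose(freq, [0.75, 0.25], atol=0.02)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            gg.roulette_probabilities([])


class TestCrossover:
    def test_probability_zero_children_equal_parents(self):
        rng = np.random.default_rng(0)
        a, b = np.arange(5.0), np.arange(5.0, 10.0)
        ca, cb = gg.real_crossover(a, b, 0.0, rng)
        np.testing.assert_array_equal(ca, a)
        np.testing.assert_array_equal(cb, b)

    def test_probability_one_full_swap(self):
        rng = np.random.default_rng(0)
        a, b = np.arange(5.0), np.arange(5.0, 10.0)
        ca, cb = gg.real_crossover(a, b, 1.0, rng)
        np.testing.assert_array_equal(ca, b)
        np.testing.assert_array_equal(cb, a)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.0, 1.0))
    def test_positionwise_multiset_preserved(self, seed, prob):
        rng = np.random.default_rng(seed)
        a = rng.random(8)
        b = rng.random(8)
        ca, cb = gg.real_crossover(a, b, prob, rng)
        for k in range(8):
            assert {ca[k], cb[k]} == {a[k], b[k]}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gg.real_crossover(np.zeros(3), np.zeros(4), 0.5,
                              np.random.default_rng(0))


class TestMutation:
    def test_zero_width_interval_unchanged(self):
        rng = np.random.default_rng(0)
        g = np.full(4, 2.0)
        out = gg.position_mutate(g, 2.0, 2.0, 0.3, rng)
        np.testing.assert_array_equal(out, g)

    def test_small_pv_replacement_uniform(self):
        """With Pv -> 0 the replacement is uniform on the bounds: empirical
        mean ~= midpoint over 10,000 draws."""
        rng = np.random.default_rng(1)
        draws = np.concatenate([
            gg.position_mutate(np.zeros(10), 2.0, 6.0, 1e-9, rng)
            for _ in range(1000)])
        assert draws.mean() == pytest.approx(4.0, abs=0.05)

    def test_output_always_within_bounds(self):
        rng = np.random.default_rng(2)
        lo, hi = -1.5, 3.5
        for _ in range(1000):
            g = rng.uniform(lo, hi, size=6)
            out = gg.position_mutate(g, lo, hi, 0.4, rng)
            assert ((out >= lo) & (out <= hi)).all()

    def test_accepted_draw_not_below_pv(self):
        """The printed redraw rule biases accepted draws to [Pv, 1)."""
        rng = np.random.default_rng(3)
        out = gg.position_mutate(np.zeros(5000), 0.0, 1.0, 0.6, rng)
        assert out.min() >= 0.6

    def test_unbiased_flag_uses_plain_uniform(self):
        rng = np.random.default_rng(4)
        out = gg.position_mutate(np.zeros(5000), 0.0, 1.0, 0.6, rng,
                                 unbiased=True)
        assert out.min() < 0.6

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            gg.position_mutate(np.zeros(3), 1.0, 0.0, 0.3,
                               np.random.default_rng(0))


class TestForecaster:
    def test_constant_series_converges_to_constant(self):
        y = np.full(200, 5.0)
        model = gg.GRUForecaster(y, None, spec=gg.ForecastSpec(window=7),
                                 hidden=8, learning_rate=0.01)
        res = model.fit(epochs=50, seed=0)
        assert res.history["mse"].iloc[-1] < 1e-3
        np.testing.assert_allclose(res.forecast(), 5.0, atol=1e-2)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        y = np.sin(np.arange(120) / 6.0) + 0.1 * rng.standard_normal(120)
        m1 = gg.GRUForecaster(y, None, hidden=8)
        m2 = gg.GRUForecaster(y, None, hidden=8)
        f1 = m1.fit(epochs=10, seed=5).forecast()
        f2 = m2.fit(epochs=10, seed=5).forecast()
        np.testing.assert_array_equal(f1, f2)

    def test_noiseless_ar_target_low_rmse(self):
        """Test RMSE below 10% of the target's standard deviation on a
        noiseless driven-AR(1) series."""
        T = 400
        drive = np.sin(np.arange(T) / 5.0)
        y = np.zeros(T)
        for t in range(1, T):
            y[t] = 0.8 * y[t - 1] + drive[t]
        model = gg.GRUForecaster(y, None, spec=gg.ForecastSpec(window=7),
                                 hidden=16, learning_rate=0.01)
        res = model.fit(epochs=150, seed=1)
        pred = res.forecast()
        target = y[7:]
        rmse = np.sqrt(np.mean((pred - target) ** 2))
        assert rmse < 0.1 * target.std()

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            gg.GRUForecaster(np.arange(5.0), None,
                             spec=gg.ForecastSpec(window=10)).fit(epochs=1)


def _planted_series(seed, T=260, n_channels=8):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((T, n_channels))
    y = np.zeros(T)
    for t in range(1, T):
        y[t] = (0.5 * y[t - 1] + 1.5 * X[t - 1, 1] - 1.2 * X[t - 1, 4]
                + 0.1 * rng.standard_normal())
    return y, X


class TestGA:
    def test_trace_monotone_non_increasing(self):
        y, X = _planted_series(0)
        res = gg.ga_optimize(y, X, ga=gg.GAConfig(population=6, generations=4,
                                                  seed=0, inner_epochs=10,
                                                  inner_patience=3))
        assert np.all(np.diff(res.trace) <= 1e-12)

    def test_two_individuals_one_generation_returns_better(self):
        y, X = _planted_series(1)
        res = gg.ga_optimize(y, X, ga=gg.GAConfig(population=2, generations=1,
                                                  seed=1, inner_epochs=5))
        assert res.best_fitness == res.fitnesses.min()
        assert res.best_fitness <= res.trace[0]

    def test_planted_feature_recovery(self):
        """The informative channels (1 and 4) enter the best mask in at
        least 2 of 3 seeds."""
        hits = 0
        for seed in (0, 1, 2):
            y, X = _planted_series(100 + seed)
            res = gg.ga_optimize(
                y, X, spec=gg.ForecastSpec(window=7),
                ga=gg.GAConfig(population=10, generations=5, seed=seed,
                               inner_epochs=20, inner_patience=4))
            mask = np.flatnonzero(res.best.mask)
            hits += (1 in mask) and (4 in mask)
        assert hits >= 2

    def test_genome_decoding_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            g = gg.Genome.random(6, rng)
            assert 4 <= g.hidden <= 32
            assert 1e-4 <= g.learning_rate <= 0.1
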