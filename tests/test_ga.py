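"""Genetic-algorithm engine: operators, invariants, convergence."""

import numpy as np
import pytest

from sigbvp import FitnessSpec, GAConfig, Population, make_example1, run_ga
from sigbvp.ga import (
    crossover_heuristic,
    init_population,
    mutate_adaptive_feasible,
    select_stochastic_uniform,
)


def sphere(V):
    return np.sum(np.asarray(V) ** 2, axis=-1)


class TestConfig:
    def test_defaults_are_benchmark_settings(self):
        cfg = GAConfig()
        assert (cfg.population_size, cfg.chromosome_length, cfg.generations) == (240, 30, 2000)
        assert (cfg.lower_bound, cfg.upper_bound) == (-15.0, 15.0)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            GAConfig(population_size=1)
        with pytest.raises(ValueError):
            GAConfig(elite_count=240)
        with pytest.raises(ValueError):
            GAConfig(lower_bound=1.0, upper_bound=-1.0)


class TestInitPopulation:
    def test_within_bounds_and_shape(self):
        cfg = GAConfig()
        V = init_population(cfg, np.random.default_rng(0))
        assert V.shape == (240, 30)
        assert (V >= -15).all() and (V <= 15).all()

    def test_same_seed_identical(self):
        cfg = GAConfig(seed=7)
        V1 = init_population(cfg, np.random.default_rng(7))
        V2 = init_population(cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(V1, V2)

    def test_degenerate_bounds_collapse_to_zero(self):
        cfg = GAConfig(lower_bound=-1e-9, upper_bound=1e-9)
        V = init_population(cfg, np.random.default_rng(1))
        assert np.max(np.abs(V)) <= 1e-9


class TestSelection:
    def test_identical_individuals_returned_verbatim(self):
        v = np.full((4, 3), 2.5)
        pop = Population(v, np.full(4, 1.0))
        sel = select_stochastic_uniform(pop, 6, np.random.default_rng(0))
        assert sel.shape == (6, 3)
        np.testing.assert_array_equal(sel, np.full((6, 3), 2.5))

    def test_zero_expectation_never_sampled(self):
        # rank scaling gives the infinite-fitness individual expectation 0
        pop = Population(np.array([[1.0], [9.0]]), np.array([0.5, np.inf]))
        for seed in range(20):
            sel = select_stochastic_uniform(pop, 2, np.random.default_rng(seed))
            np.testing.assert_array_equal(sel, [[1.0], [1.0]])

    def test_all_infinite_population_errors(self):
        pop = Population(np.zeros((3, 2)), np.full(3, np.inf))
        with pytest.raises(ValueError):
            select_stochastic_uniform(pop, 2, np.random.default_rng(0))

    def test_empirical_frequencies_match_rank_expectations(self):
        """SUS sampling frequencies track the 1/sqrt(rank) expectations."""
        fitnesses = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        pop = Population(np.arange(5.0)[:, None], fitnesses)
        expect = (1.0 / np.sqrt(np.arange(1, 6)))
        probs = expect / expect.sum()
        counts = np.zeros(5)
        n_draws, k = 1000, 10
        rng = np.random.default_rng(42)
        for _ in range(n_draws):
            sel = select_stochastic_uniform(pop, k, rng)
            for v in sel[:, 0]:
                counts[int(v)] += 1
        total = n_draws * k
        for i in range(5):
            sigma = np.sqrt(total * probs[i] * (1 - probs[i]))
            assert abs(counts[i] - total * probs[i]) < 3 * sigma + k


class TestCrossover:
    def test_identical_parents_fixed_point(self):
        p = np.array([1.0, -2.0, 3.0])
        child = crossover_heuristic(p, p.copy(), 1.2, np.random.default_rng(0))
        np.testing.assert_allclose(child, p)

    def test_child_lies_past_better_parent_interval(self):
        """1-D: p1=0 better, p2=10, R=1.2 -> child in (-2, 10), clipped to box."""
        rng = np.random.default_rng(3)
        children = [crossover_heuristic(np.array([0.0]), np.array([10.0]), 1.2, rng)[0]
                    for _ in range(1000)]
        children = np.asarray(children)
        assert (children > -2.0).all() and (children < 10.0).all()
        assert (children < 0.0).any()  # overshoot beyond the better parent occurs

    def test_result_respects_bounds(self):
        rng = np.random.default_rng(5)
        child = crossover_heuristic(np.array([-15.0]), np.array([15.0]), 2.0, rng,
                                    bounds=(-15, 15))
        assert -15.0 <= child[0] <= 15.0


class TestMutation:
    def test_zero_scale_is_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        out = mutate_adaptive_feasible(v, 0.0, (-15, 15), np.random.default_rng(0))
        np.testing.assert_array_equal(out, v)

    def test_output_always_within_bounds(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            v = rng.uniform(-15, 15, 50)
            out = mutate_adaptive_feasible(v, 1.0, (-15, 15), rng)
            assert (out >= -15).all() and (out <= 15).all()

    def test_displacement_grows_with_scale(self):
        rng = np.random.default_rng(11)
        v = np.zeros(30)
        means = []
        for scale in (0.1, 0.5, 1.0):
            d = [np.abs(mutate_adaptive_feasible(v, scale, (-15, 15), rng) - v).mean()
                 for _ in range(3000)]
            means.append(np.mean(d))
        assert means[0] < means[1] < means[2]


class TestRunGA:
    def test_sphere_convergence(self):
        cfg = GAConfig(population_size=100, chromosome_length=6, generations=200,
                       lower_bound=-5, upper_bound=5, seed=1)
        run = run_ga(None, None, cfg, objective=sphere)
        assert run.best_fitness < 1e-2

    def test_trace_non_increasing(self):
        cfg = GAConfig(population_size=60, generations=120, seed=3)
        run = run_ga(make_example1(), FitnessSpec(), cfg)
        vals = [t[1] for t in run.trace]
        assert all(b <= a + 1e-18 for a, b in zip(vals, vals[1:]))

    def test_identical_seed_identical_trace(self):
        cfg = GAConfig(population_size=40, generations=60, seed=9)
        p, spec = make_example1(), FitnessSpec()
        r1 = run_ga(p, spec, cfg)
        r2 = run_ga(p, spec, cfg)
        assert r1.trace == r2.trace
        np.testing.assert_array_equal(r1.best, r2.best)

    def test_best_within_bounds(self):
        cfg = GAConfig(population_size=50, generations=80, seed=5)
        run = run_ga(make_example1(), FitnessSpec(), cfg)
        assert (run.best >= -15).all() and (run.best <= 15).all()

    def test_stall_stops_early(self):
        cfg = GAConfig(population_size=30, chromosome_length=3, generations=2000,
                       stall_generations=20, function_tolerance=1e-3,
                       lower_bound=-1, upper_bound=1, seed=2)
        run = run_ga(None, None, cfg, objective=sphere)
        assert run.generations_run < 2000
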