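"""Genetic-algorithm operators and the generational loop."""

import numpy as np
import pytest
from scipy import stats

from cardiofit.ga import (
    GAConfig, Organism, ToyModel, cauchy_vector_mutation, elitism, evaluate,
    init_population, run, sbx_crossover, tournament_select,
)
from cardiofit.waveform import PENALTY_RMSE


@pytest.fixture
def toy_spec(toy_baselines):
    return ToyModel().genome_spec(toy_baselines.pcls)


class TestInitPopulation:
    def test_seeded_reproducibility(self, toy_spec):
        cfg = GAConfig(population=30, generations=1, model="toy", seed=42)
        model = ToyModel()
        p1 = init_population(cfg, toy_spec, model)
        p2 = init_population(cfg, toy_spec, model)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.genome, b.genome)

    def test_bounds_and_log_uniform_median(self, toy_spec):
        cfg = GAConfig(population=2500, generations=1, model="toy", seed=0)
        pop = init_population(cfg, toy_spec, ToyModel())
        G = np.array([o.genome for o in pop])
        assert G.min() >= 0.01 and G.max() <= 4.0
        # log-uniform on [0.01, 4] has median sqrt(0.04) = 0.2
        assert np.median(G) == pytest.approx(0.2, rel=0.15)


class TestSBX:
    def test_identical_parents_identical_children(self, toy_spec):
        rng = np.random.default_rng(0)
        p = np.array([1.0, 2.0, 0.5, 1.5])
        c1, c2 = sbx_crossover(p, p, toy_spec, rng)
        np.testing.assert_allclose(c1, p)
        np.testing.assert_allclose(c2, p)

    def test_children_symmetric_about_parent_mean(self, toy_spec):
        rng = np.random.default_rng(1)
        a = np.array([1.0, 2.0, 0.5, 1.5])
        b = np.array([2.0, 1.0, 1.5, 0.5])
        for _ in range(50):
            c1, c2 = sbx_crossover(a, b, toy_spec, rng)
            np.testing.assert_allclose(c1 + c2, a + b, rtol=1e-12)

    def test_spread_factor_distribution_matches_polynomial_law(self):
        """KS test of sampled spread factors against the analytic CDF of
        the order-eta polynomial distribution."""
        from cardiofit.ga import _sbx_beta
        eta = 10.0
        rng = np.random.default_rng(123)
        samples = np.array([_sbx_beta(rng.random(), eta)
                            for _ in range(100_000)])

        def cdf(beta):
            beta = np.asarray(beta, dtype=float)
            lo = 0.5 * np.power(np.clip(beta, 0, None), eta + 1.0)
            hi = 1.0 - 0.5 * np.power(np.clip(beta, 1e-12, None),
                                      -(eta + 1.0))
            return np.where(beta <= 1.0, lo, hi)

        d, p = stats.kstest(samples, cdf)
        assert p > 0.01


class TestCauchyMutation:
    def _wide_spec(self):
        from cardiofit.ga import GenomeSpec
        n = 6
        return GenomeSpec(tuple(f"p{i}" for i in range(n)),
                          np.ones(n), np.full(n, -1e9), np.full(n, 1e9))

    def test_step_magnitude_hwhm(self):
        """Far from any bound the step length |r| has median = gamma."""
        spec = self._wide_spec()
        rng = np.random.default_rng(7)
        g = np.ones(6)
        steps = []
        for _ in range(20_000):
            out = cauchy_vector_mutation(g, spec, rng, gamma=0.18)
            steps.append(np.linalg.norm(out - g))
        assert np.median(steps) == pytest.approx(0.18, rel=0.1)

    def test_bounds_never_violated_fuzz(self, toy_spec):
        rng = np.random.default_rng(99)
        g = np.exp(rng.uniform(np.log(0.01), np.log(4.0), size=4))
        for _ in range(20_000):
            g = cauchy_vector_mutation(g, toy_spec, rng, gamma=0.18)
            assert np.all(g >= toy_spec.lo - 1e-12)
            assert np.all(g <= toy_spec.hi + 1e-12)

    def test_mutation_moves_all_genes_together(self, toy_spec):
        rng = np.random.default_rng(5)
        g = np.ones(4)
        out = cauchy_vector_mutation(g, toy_spec, rng, gamma=0.18)
        # vector mutation: every component moves (direction has full support)
        assert np.all(out != g)


class TestTournament:
    def _pop(self, fits):
        out = []
        for f in fits:
            o = Organism(np.zeros(1))
            o.fitness = f
            out.append(o)
        return out

    def test_equal_fitness_pool_is_resampling(self):
        pop = self._pop([1.0] * 8)
        pool = tournament_select(pop, np.random.default_rng(0))
        assert len(pool) == 8
        assert all(o in pop for o in pool)

    def test_selection_pressure_lowers_mean_fitness(self):
        rng = np.random.default_rng(1)
        pop = self._pop(list(rng.uniform(0, 10, size=40)))
        pool = tournament_select(pop, rng)
        assert (np.mean([o.fitness for o in pool])
                <= np.mean([o.fitness for o in pop]))

    def test_best_count_matches_exact_enumeration(self):
        """With two shuffled copies, the best organism enters the pool once
        when paired against itself (probability 1/n) and twice otherwise:
        expected count 2 - 1/n, verified by exhaustive enumeration at n=4
        and approached empirically."""
        import itertools
        n = 4
        total = 0
        cases = 0
        for p1 in itertools.permutations(range(n)):
            for p2 in itertools.permutations(range(n)):
                count = sum(1 for a, b in zip(p1, p2) if 0 in (a, b))
                total += count
                cases += 1
        exact = total / cases
        assert exact == pytest.approx(2.0 - 1.0 / n)
        pop = self._pop([0.0, 5.0, 6.0, 7.0])   # organism 0 is best
        rng = np.random.default_rng(2)
        counts = []
        for _ in range(3000):
            pool = tournament_select(pop, rng)
            counts.append(sum(1 for o in pool if o is pop[0]))
        assert np.mean(counts) == pytest.approx(exact, abs=0.05)


class TestElitism:
    def _pop(self, fits):
        out = []
        for f in fits:
            o = Organism(np.array([f]))
            o.fitness = f
            out.append(o)
        return out

    def test_zero_elites_leaves_offspring_unchanged(self):
        prev = self._pop([1, 2, 3, 4])
        off = self._pop([5, 6, 7, 8])
        assert elitism(prev, off, 0) is off

    def test_best_previous_replace_worst_offspring(self):
        prev = self._pop([1.0, 2.0, 3.0, 4.0])
        off = self._pop([10.0, 0.5, 20.0, 5.0])
        out = elitism(prev, off, 2)
        fits = sorted(o.fitness for o in out)
        assert fits == [0.5, 1.0, 2.0, 5.0]

    def test_elite_count_must_be_smaller_than_population(self):
        pop = self._pop([1, 2])
        with pytest.raises(ValueError):
            elitism(pop, pop, 2)

    def test_static_model_best_fitness_never_increases(self, toy_baselines):
        cfg = GAConfig(population=24, generations=30, model="toy", seed=3)
        h = run(cfg, toy_baselines)
        assert np.all(np.diff(h.best_fitness) <= 1e-12)


class TestEvaluate:
    def test_truth_genome_scores_zero_on_toy(self, toy_baselines, toy_truth):
        model = ToyModel()
        spec = model.genome_spec(toy_baselines.pcls)
        org = Organism(toy_truth.copy())
        org.states = {p: None for p in toy_baselines.pcls}
        cfg = GAConfig(population=2, generations=1, model="toy", seed=0)
        evaluate(org, toy_baselines, spec, model, cfg)
        assert org.fitness == pytest.approx(0.0, abs=1e-12)
        assert set(org.per_pcl) == set(toy_baselines.pcls)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(n_beats=8)          # must be odd
        with pytest.raises(ValueError):
            GAConfig(crossover_p=1.5)
        with pytest.raises(ValueError):
            GAConfig(elite_fraction=1.0)


class TestCableMode:
    def test_cable_evaluation_round_trip(self):
        """A tiny cable organism evaluates end-to-end: per-cell states are
        persisted and the slow-variable genes are written back."""
        from cardiofit.ga import CableModel
        from cardiofit.personalize import make_baselines
        from cardiofit.tissue1d import CableConfig
        pcls = (500.0,)
        bl, _ = make_baselines(None, pcls=pcls, settle=10.0,
                               mode="absolute")
        model = CableModel(config=CableConfig(n_cells=3, record_cell=1,
                                              boundary_margin=0))
        spec = model.genome_spec(pcls)
        cfg = GAConfig(population=2, generations=1, model="cable", seed=0,
                       n_beats=3)
        g = np.ones(spec.size)
        g[spec.slow_index(500.0, "nai")] = 7.0
        g[spec.slow_index(500.0, "cansr")] = 1.2
        org = Organism(g.copy())
        org.states = {500.0: model.initial_state(g, spec, 500.0)}
        evaluate(org, bl, spec, model, cfg)
        assert org.fitness is not None and org.fitness < PENALTY_RMSE
        assert org.states[500.0].shape[0] == 3
        # write-back moved the slow genes toward the cable's actual state
        assert org.genome[spec.slow_index(500.0, "nai")] != 7.0


class TestRun:
    def test_same_seed_bit_identical_history(self, toy_baselines):
        cfg = GAConfig(population=20, generations=15, model="toy", seed=11)
        h1 = run(cfg, toy_baselines)
        h2 = run(cfg, toy_baselines)
        assert h1.best_fitness == h2.best_fitness
        np.testing.assert_array_equal(h1.best.genome, h2.best.genome)

    def test_bounds_hold_through_whole_run(self, toy_baselines):
        cfg = GAConfig(population=20, generations=25, model="toy", seed=13,
                       snapshot_every=5)
        h = run(cfg, toy_baselines)
        for snap in h.snapshots.values():
            assert snap.min() >= 0.01 - 1e-12
            assert snap.max() <= 4.0 + 1e-12

    def test_fitness_improves_on_toy_problem(self, toy_baselines):
        cfg = GAConfig(population=30, generations=40, model="toy", seed=17)
        h = run(cfg, toy_baselines)
        assert h.best_fitness[-1] < 0.2 * h.best_fitness[0]
        assert h.best.fitness < PENALTY_RMSE
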