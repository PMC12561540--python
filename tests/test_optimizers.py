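import numpy as np
import pytest
from scipy import stats as sps

from efsel.optimizers import (
    ConfigError,
    Individual,
    OptimizerConfig,
    de_rand_1_bin,
    de_select,
    evolve,
    initialize_population,
    jde_adapt,
    pso_step,
    random_search_step,
)
from efsel.threshold_control import make_controller


def mean_genotype_evaluator(ind, theta):
    """Analytic objective: fitness = mean gene value (minimum at the origin)."""
    ind.fitness = float(ind.genotype.mean())
    ind.accuracy = 0.0
    ind.subset_size = int((ind.genotype >= theta).sum())


class TestInitialization:
    def test_population_size_and_range(self, rng):
        pop = initialize_population(10, OptimizerConfig(), False, rng)
        assert len(pop) == 30
        for ind in pop:
            assert ind.genotype.shape == (10,)
            assert np.all((0 <= ind.genotype) & (ind.genotype <= 1))
            assert ind.theta_gene is None

    def test_same_seed_identical(self):
        a = initialize_population(5, OptimizerConfig(), True, np.random.default_rng(3))
        b = initialize_population(5, OptimizerConfig(), True, np.random.default_rng(3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.genotype, y.genotype)
            assert x.theta_gene == y.theta_gene

    def test_sa_mode_adds_theta_gene_in_bounds(self, rng):
        pop = initialize_population(5, OptimizerConfig(), True, rng)
        assert all(0.1 <= ind.theta_gene <= 0.9 for ind in pop)

    def test_jde_strategy_parameters_initialized(self, rng):
        pop = initialize_population(5, OptimizerConfig(algorithm="jDE"), False, rng)
        assert all(ind.F == 0.5 and ind.CR == 0.9 for ind in pop)

    def test_budget_below_population_rejected(self):
        with pytest.raises(ConfigError):
            OptimizerConfig(population_size=30, max_evaluations=10)

    def test_de_needs_four_members(self):
        with pytest.raises(ConfigError):
            OptimizerConfig(algorithm="DE", population_size=3)


class TestDeOperators:
    def test_zero_difference_vector_with_full_crossover(self, rng):
        x1, x2 = np.array([0.3, 0.6]), np.array([0.8, 0.2])
        trial = de_rand_1_bin(np.array([0.5, 0.5]), (x1, x2, x2), 0.5, 1.0, rng)
        np.testing.assert_allclose(trial, x1)

    def test_cr_zero_changes_exactly_one_coordinate(self, rng):
        target = np.full(20, 0.5)
        donors = tuple(np.full(20, v) for v in (0.1, 0.9, 0.2))
        trial = de_rand_1_bin(target, donors, 0.5, 0.0, rng)
        assert np.sum(trial != target) == 1

    def test_mutation_arithmetic(self, rng):
        trial = de_rand_1_bin(
            np.array([0.0]),
            (np.array([0.5]), np.array([0.9]), np.array([0.1])),
            0.5,
            1.0,
            rng,
        )
        assert trial[0] == pytest.approx(0.9)

    def test_selection_prefers_trial_on_tie(self):
        parent = Individual(genotype=np.zeros(2), fitness=0.3)
        better = Individual(genotype=np.ones(2), fitness=0.2)
        equal = Individual(genotype=np.ones(2), fitness=0.3)
        worse = Individual(genotype=np.ones(2), fitness=0.4)
        assert de_select(parent, better) is better
        assert de_select(parent, equal) is equal
        assert de_select(parent, worse) is parent


class TestJdeAdaptation:
    def test_zero_probabilities_inherit(self, rng):
        assert jde_adapt(0.42, 0.77, 0.1, 0.9, 0.0, 0.0, rng) == (0.42, 0.77)

    def test_unit_probabilities_regenerate_in_range(self, rng):
        for _ in range(200):
            F, CR = jde_adapt(0.42, 0.77, 0.1, 0.9, 1.0, 1.0, rng)
            assert 0.1 <= F <= 1.0
            assert 0.0 <= CR <= 1.0

    def test_regeneration_frequency_matches_tau(self, rng):
        tau = 0.1
        n = 10_000
        hits = sum(
            jde_adapt(0.5, 0.9, 0.1, 0.9, tau, tau, rng)[0] != 0.5 for _ in range(n)
        )
        sigma = np.sqrt(n * tau * (1 - tau))
        assert abs(hits - n * tau) < 3 * sigma


class TestPsoAndRandomSearch:
    def test_stationary_at_consensus(self, rng):
        x = np.array([[0.4, 0.6]])
        moved, v = pso_step(x, np.zeros_like(x), x.copy(), x[0], 0.7, 1.5, 1.5, rng)
        np.testing.assert_allclose(moved, x)
        np.testing.assert_allclose(v, 0.0)

    def test_zero_coefficients_freeze_swarm(self, rng):
        x = np.array([[0.4, 0.6], [0.1, 0.9]])
        moved, _ = pso_step(x, np.zeros_like(x), np.ones_like(x), np.ones(2),
                            0.0, 0.0, 0.0, rng)
        np.testing.assert_allclose(moved, x)

    def test_single_particle_moves_toward_gbest(self, rng):
        x = np.array([[0.2]])
        gbest = np.array([0.8])
        moved, _ = pso_step(x, np.zeros_like(x), x.copy(), gbest, 0.0, 0.0, 1.5, rng)
        assert moved[0, 0] >= 0.2  # pull is non-negative toward gbest

    def test_random_search_range_and_determinism(self):
        a = random_search_step(8, np.random.default_rng(5))
        b = random_search_step(8, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)
        assert np.all((0 <= a) & (a <= 1))

    def test_random_search_uniform_marginals(self):
        rng = np.random.default_rng(6)
        samples = np.array([random_search_step(1, rng)[0] for _ in range(10_000)])
        _, p = sps.kstest(samples, "uniform")
        assert p > 0.01


class TestEvolve:
    def test_budget_floor_runs_initialization_only(self):
        cfg = OptimizerConfig(population_size=10, max_evaluations=10)
        rec = evolve(cfg, make_controller("STATIC"), mean_genotype_evaluator, 5, seed=0)
        assert rec.generations == 1  # generation 0 only
        assert rec.evaluations[-1] == 10
        assert rec.gtc is None  # assigned by the runner; trace has length 1

    @pytest.mark.parametrize("algorithm", ["DE", "jDE"])
    def test_elitist_best_trace_non_increasing(self, algorithm):
        cfg = OptimizerConfig(algorithm=algorithm, population_size=10,
                              max_evaluations=300)
        rec = evolve(cfg, make_controller("STATIC"), mean_genotype_evaluator, 12, seed=1)
        trace = rec.best_fitness
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_jde_minimizes_analytic_objective(self):
        cfg = OptimizerConfig(algorithm="jDE", population_size=30,
                              max_evaluations=3000)
        rec = evolve(cfg, make_controller("STATIC"), mean_genotype_evaluator, 20, seed=2)
        assert rec.best_fitness[-1] < 0.05

    def test_budget_conservation(self):
        for budget in (90, 95, 100):
            cfg = OptimizerConfig(algorithm="jDE", population_size=10,
                                  max_evaluations=budget)
            rec = evolve(cfg, make_controller("STATIC"), mean_genotype_evaluator,
                         6, seed=3)
            assert rec.evaluations[-1] <= budget

    def test_identical_seed_identical_record(self):
        cfg = OptimizerConfig(algorithm="jDE", population_size=8, max_evaluations=200)
        recs = [
            evolve(cfg, make_controller("SRA"), mean_genotype_evaluator, 7, seed=4)
            for _ in range(2)
        ]
        assert recs[0].best_fitness == recs[1].best_fitness
        assert recs[0].mean_theta == recs[1].mean_theta
        np.testing.assert_array_equal(
            recs[0].best_individual.genotype, recs[1].best_individual.genotype
        )

    @pytest.mark.parametrize("algorithm", ["DE", "jDE", "PSO", "RS"])
    def test_genotypes_and_theta_genes_stay_projected(self, algorithm):
        seen = []

        def recording_evaluator(ind, theta):
            seen.append((ind.genotype.copy(), ind.theta_gene))
            mean_genotype_evaluator(ind, theta)

        cfg = OptimizerConfig(algorithm=algorithm, population_size=6,
                              max_evaluations=120)
        evolve(cfg, make_controller("SA"), recording_evaluator, 5, seed=5)
        for genotype, theta_gene in seen:
            assert np.all((0 <= genotype) & (genotype <= 1))
            assert 0.1 <= theta_gene <= 0.9
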