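"""Bio-inspired optimizers over real genotypes, with optional threshold gene.

All backends share the generic population loop

    initialize -> evaluate -> while budget: modify / evaluate trials /
    select survivors / track global best,

differing only in how they modify individuals. Implemented backends:

* ``jDE``  — differential evolution with per-individual self-adapted F and CR
             (regenerated with probabilities tau1/tau2, inherited on success);
* ``DE``   — classic DE/rand/1/bin with fixed F and CR;
* ``PSO``  — inertia-weight particle swarm with clamped velocities;
* ``RS``   — random search (fresh uniform samples, global best tracked).

In self-adaptive (SA) threshold mode each genome carries one extra gene —
the individual's own threshold — which passes through the same variation
operators as the problem variables and is then projected into the threshold
bounds. The registry accepts externally supplied backends so other
population methods can plug in without changes here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .threshold_control import (
    PopulationSummary,
    ThresholdBounds,
    ThresholdController,
    compute_selection_rate,
    compute_success_rate,
)

__all__ = [
    "Individual",
    "OptimizerConfig",
    "RunRecord",
    "ConfigError",
    "initialize_population",
    "de_rand_1_bin",
    "jde_adapt",
    "de_select",
    "pso_step",
    "random_search_step",
    "evolve",
    "OPTIMIZER_REGISTRY",
    "register_optimizer",
]


class ConfigError(ValueError):
    pass


@dataclass
class Individual:
    """One candidate solution: genotype in [0,1]^n plus optional extras."""

    genotype: np.ndarray
    theta_gene: float | None = None
    F: float | None = None
    CR: float | None = None
    fitness: float = np.inf
    accuracy: float = 0.0
    subset_size: int = 0

    def copy(self) -> "Individual":
        return Individual(
            genotype=self.genotype.copy(),
            theta_gene=self.theta_gene,
            F=self.F,
            CR=self.CR,
            fitness=self.fitness,
            accuracy=self.accuracy,
            subset_size=self.subset_size,
        )


@dataclass(frozen=True)
class OptimizerConfig:
    """Algorithm choice plus shared and algorithm-specific constants."""

    algorithm: str = "jDE"
    population_size: int = 30
    max_evaluations: int = 3000
    # DE
    F: float = 0.5
    CR: float = 0.9
    # jDE self-adaptation
    F_lower: float = 0.1
    F_upper: float = 0.9
    tau1: float = 0.1
    tau2: float = 0.1
    # PSO
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5

    def __post_init__(self) -> None:
        if self.algorithm not in OPTIMIZER_REGISTRY:
            raise ConfigError(
                f"unknown algorithm {self.algorithm!r}; "
                f"registered: {sorted(OPTIMIZER_REGISTRY)}"
            )
        if self.algorithm in ("DE", "jDE") and self.population_size < 4:
            raise ConfigError("DE variants need a population of at least 4")
        if self.population_size < 1:
            raise ConfigError("population_size must be positive")
        if self.max_evaluations < self.population_size:
            raise ConfigError("budget must cover at least the initial population")


@dataclass
class RunRecord:
    """Everything one optimization run produced, generation by generation."""

    best_fitness: list[float] = field(default_factory=list)
    mean_theta: list[float] = field(default_factory=list)
    selection_rate: list[float] = field(default_factory=list)
    success_rate: list[float] = field(default_factory=list)
    evaluations: list[int] = field(default_factory=list)
    best_individual: Individual | None = None
    best_theta: float = 0.5
    test_accuracy: float | None = None
    test_subset_size: int | None = None
    gtc: int | None = None
    seed: int | None = None

    @property
    def generations(self) -> int:
        return len(self.best_fitness)

    def to_dict(self) -> dict:
        best = self.best_individual
        return {
            "seed": self.seed,
            "best_fitness": [float(v) for v in self.best_fitness],
            "mean_theta": [float(v) for v in self.mean_theta],
            "selection_rate": [float(v) for v in self.selection_rate],
            "success_rate": [float(v) for v in self.success_rate],
            "evaluations": [int(v) for v in self.evaluations],
            "best": None
            if best is None
            else {
                "genotype": [float(v) for v in best.genotype],
                "theta_gene": best.theta_gene,
                "fitness": float(best.fitness),
                "accuracy": float(best.accuracy),
                "subset_size": int(best.subset_size),
            },
            "best_theta": float(self.best_theta),
            "test_accuracy": self.test_accuracy,
            "test_subset_size": self.test_subset_size,
            "gtc": self.gtc,
        }


def _project_unit(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def initialize_population(
    n: int,
    cfg: OptimizerConfig,
    sa_mode: bool,
    rng: np.random.Generator,
    bounds: ThresholdBounds | None = None,
) -> list[Individual]:
    """Uniform random population; jDE strategy parameters start at F=0.5, CR=0.9."""
    if n < 1:
        raise ConfigError("need at least one decision variable")
    bounds = bounds or ThresholdBounds()
    pop = []
    for _ in range(cfg.population_size):
        genotype = rng.uniform(0.0, 1.0, size=n)
        theta_gene = (
            float(rng.uniform(bounds.theta_min, bounds.theta_max)) if sa_mode else None
        )
        ind = Individual(genotype=genotype, theta_gene=theta_gene)
        if cfg.algorithm == "jDE":
            ind.F, ind.CR = 0.5, 0.9
        pop.append(ind)
    return pop


def de_rand_1_bin(
    target: np.ndarray,
    donors: tuple[np.ndarray, np.ndarray, np.ndarray],
    F: float,
    CR: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """DE/rand/1/bin on a raw vector: v = x1 + F (x2 - x3), binomial crossover.

    The caller projects the result (problem genes into [0,1], the trailing
    threshold gene — if any — into its own bounds).
    """
    x1, x2, x3 = donors
    v = x1 + F * (x2 - x3)
    n = target.shape[0]
    cross = rng.uniform(size=n) < CR
    cross[rng.integers(n)] = True  # j_rand guarantees one donor coordinate
    return np.where(cross, v, target)


def jde_adapt(
    F: float,
    CR: float,
    F_lower: float,
    F_upper: float,
    tau1: float,
    tau2: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """jDE rule: regenerate F with prob tau1 (uniform on [Fl, Fl+Fu]), CR with prob tau2."""
    if F_lower <= 0 or F_upper <= 0:
        raise ConfigError("F_lower and F_upper must be positive")
    if not (0.0 <= tau1 <= 1.0 and 0.0 <= tau2 <= 1.0):
        raise ConfigError("tau1 and tau2 must lie in [0,1]")
    r1, r2, r3, r4 = rng.uniform(size=4)
    F_new = F_lower + r2 * F_upper if r1 < tau1 else F
    CR_new = r4 if r3 < tau2 else CR
    return float(F_new), float(CR_new)


def de_select(parent: Individual, trial: Individual) -> Individual:
    """Greedy DE selection under minimization; ties go to the trial."""
    return trial if trial.fitness <= parent.fitness else parent


def pso_step(
    positions: np.ndarray,
    velocities: np.ndarray,
    personal_bests: np.ndarray,
    global_best: np.ndarray,
    inertia: float,
    cognitive: float,
    social: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical inertia-weight velocity/position update, vectorized over the swarm."""
    r1 = rng.uniform(size=positions.shape)
    r2 = rng.uniform(size=positions.shape)
    velocities = (
        inertia * velocities
        + cognitive * r1 * (personal_bests - positions)
        + social * r2 * (global_best[None, :] - positions)
    )
    np.clip(velocities, -1.0, 1.0, out=velocities)
    return positions + velocities, velocities


def random_search_step(n: int, rng: np.random.Generator) -> np.ndarray:
    """A fresh uniform sample of the unit hypercube."""
    return rng.uniform(0.0, 1.0, size=n)


# ---------------------------------------------------------------------------
# The generic loop (Algorithm-1 style) with pluggable modification backends.
# ---------------------------------------------------------------------------


class _EvolveContext:
    """Budget accounting plus evaluation plumbing shared by the backends."""

    def __init__(self, evaluator, controller, budget, bounds, n):
        self.evaluator = evaluator
        self.controller = controller
        self.budget = budget
        self.bounds = bounds
        self.n = n
        self.used = 0

    def theta_for(self, ind: Individual) -> float:
        if self.controller.is_self_adaptive:
            return float(ind.theta_gene)
        return self.controller.theta

    def can_evaluate(self) -> bool:
        return self.used < self.budget

    def evaluate(self, ind: Individual) -> None:
        self.evaluator(ind, self.theta_for(ind))
        self.used += 1

    def project_theta_gene(self, ind: Individual) -> None:
        if ind.theta_gene is not None:
            ind.theta_gene = min(
                max(ind.theta_gene, self.bounds.theta_min), self.bounds.theta_max
            )


def _full_vector(ind: Individual) -> np.ndarray:
    if ind.theta_gene is None:
        return ind.genotype
    return np.append(ind.genotype, ind.theta_gene)


def _split_vector(v: np.ndarray, n: int, sa_mode: bool) -> tuple[np.ndarray, float | None]:
    if sa_mode:
        return v[:n], float(v[n])
    return v, None


def _de_generation(
    pop: list[Individual],
    cfg: OptimizerConfig,
    ctx: _EvolveContext,
    rng: np.random.Generator,
    self_adaptive_FCR: bool,
) -> list[Individual]:
    """One generation of DE/rand/1/bin (or jDE when self_adaptive_FCR)."""
    np_ = len(pop)
    sa_mode = ctx.controller.is_self_adaptive
    new_pop = list(pop)
    for i in range(np_):
        if not ctx.can_evaluate():
            break
        if self_adaptive_FCR:
            F, CR = jde_adapt(
                pop[i].F, pop[i].CR, cfg.F_lower, cfg.F_upper, cfg.tau1, cfg.tau2, rng
            )
        else:
            F, CR = cfg.F, cfg.CR
        choices = [j for j in range(np_) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        trial_vec = de_rand_1_bin(
            _full_vector(pop[i]),
            (_full_vector(pop[r1]), _full_vector(pop[r2]), _full_vector(pop[r3])),
            F,
            CR,
            rng,
        )
        genes, theta_gene = _split_vector(trial_vec, ctx.n, sa_mode)
        trial = Individual(genotype=_project_unit(genes), theta_gene=theta_gene)
        ctx.project_theta_gene(trial)
        if self_adaptive_FCR:
            trial.F, trial.CR = F, CR
        ctx.evaluate(trial)
        new_pop[i] = de_select(pop[i], trial)
    return new_pop


class _PSOState:
    def __init__(self, pop: list[Individual], ctx: _EvolveContext):
        self.velocities = np.zeros((len(pop), ctx.n + (1 if pop[0].theta_gene is not None else 0)))
        self.pbest = [ind.copy() for ind in pop]

    def gbest(self) -> Individual:
        return min(self.pbest, key=lambda ind: ind.fitness)


def _pso_generation(
    pop: list[Individual],
    cfg: OptimizerConfig,
    ctx: _EvolveContext,
    rng: np.random.Generator,
    state: _PSOState,
) -> list[Individual]:
    sa_mode = ctx.controller.is_self_adaptive
    positions = np.stack([_full_vector(ind) for ind in pop])
    pbest_pos = np.stack([_full_vector(ind) for ind in state.pbest])
    gbest_pos = _full_vector(state.gbest())
    moved, state.velocities = pso_step(
        positions,
        state.velocities,
        pbest_pos,
        gbest_pos,
        cfg.inertia,
        cfg.cognitive,
        cfg.social,
        rng,
    )
    new_pop = list(pop)
    for i in range(len(pop)):
        if not ctx.can_evaluate():
            break
        genes, theta_gene = _split_vector(moved[i], ctx.n, sa_mode)
        ind = Individual(genotype=_project_unit(genes), theta_gene=theta_gene)
        ctx.project_theta_gene(ind)
        ctx.evaluate(ind)
        new_pop[i] = ind
        if ind.fitness <= state.pbest[i].fitness:
            state.pbest[i] = ind.copy()
    return new_pop


def _rs_generation(
    pop: list[Individual],
    cfg: OptimizerConfig,
    ctx: _EvolveContext,
    rng: np.random.Generator,
) -> list[Individual]:
    sa_mode = ctx.controller.is_self_adaptive
    new_pop = list(pop)
    for i in range(len(pop)):
        if not ctx.can_evaluate():
            break
        genotype = random_search_step(ctx.n, rng)
        theta_gene = (
            float(rng.uniform(ctx.bounds.theta_min, ctx.bounds.theta_max))
            if sa_mode
            else None
        )
        ind = Individual(genotype=genotype, theta_gene=theta_gene)
        ctx.evaluate(ind)
        new_pop[i] = ind
    return new_pop


OPTIMIZER_REGISTRY: dict[str, Callable] = {}


def register_optimizer(name: str, factory: Callable) -> None:
    """Register an external backend.

    ``factory(cfg, ctx)`` must return a callable
    ``generation(pop, rng) -> new_pop`` that evaluates trials through
    ``ctx.evaluate`` (this is what enforces the budget)."""
    OPTIMIZER_REGISTRY[name] = factory


def _make_de(cfg, ctx):
    return lambda pop, rng: _de_generation(pop, cfg, ctx, rng, self_adaptive_FCR=False)


def _make_jde(cfg, ctx):
    return lambda pop, rng: _de_generation(pop, cfg, ctx, rng, self_adaptive_FCR=True)


def _make_pso(cfg, ctx):
    state = {}

    def generation(pop, rng):
        if "s" not in state:
            state["s"] = _PSOState(pop, ctx)
        return _pso_generation(pop, cfg, ctx, rng, state["s"])

    return generation


def _make_rs(cfg, ctx):
    return lambda pop, rng: _rs_generation(pop, cfg, ctx, rng)


OPTIMIZER_REGISTRY.update(
    {"DE": _make_de, "jDE": _make_jde, "PSO": _make_pso, "RS": _make_rs}
)


def _population_theta(pop: list[Individual], controller: ThresholdController):
    if controller.is_self_adaptive:
        return np.array([ind.theta_gene for ind in pop])
    return controller.theta


def evolve(
    cfg: OptimizerConfig,
    controller: ThresholdController,
    evaluator: Callable[[Individual, float], object],
    n_features: int,
    seed: int,
    bounds: ThresholdBounds | None = None,
) -> RunRecord:
    """Run one optimization under an evaluation budget; returns the trace.

    The root seed is split into independent substreams for initialization
    and variation so a run replays exactly. Global controllers update once
    per generation, after all trial evaluations; the threshold is frozen
    within a generation. Fitness values are never recomputed when a global
    threshold moves (stale-best policy).
    """
    bounds = bounds or ThresholdBounds()
    root = np.random.default_rng(seed)
    init_rng, var_rng = root.spawn(2)

    ctx = _EvolveContext(evaluator, controller, cfg.max_evaluations, bounds, n_features)
    pop = initialize_population(
        n_features, cfg, controller.is_self_adaptive, init_rng, bounds
    )
    for ind in pop:
        ctx.evaluate(ind)

    record = RunRecord(seed=seed)
    best = min(pop, key=lambda ind: ind.fitness).copy()
    best_theta = ctx.theta_for(best)

    def log_generation(success_rate: float) -> None:
        theta = _population_theta(pop, controller)
        record.best_fitness.append(best.fitness)
        record.mean_theta.append(float(np.mean(theta)))
        record.selection_rate.append(
            compute_selection_rate(np.stack([ind.genotype for ind in pop]), theta)
        )
        record.success_rate.append(success_rate)
        record.evaluations.append(ctx.used)

    log_generation(0.0)

    generation = OPTIMIZER_REGISTRY[cfg.algorithm](cfg, ctx)
    while ctx.can_evaluate():
        prev_fitness = np.array([ind.fitness for ind in pop])
        pop = generation(pop, var_rng)
        now_fitness = np.array([ind.fitness for ind in pop])
        sr = compute_success_rate(now_fitness, prev_fitness)

        gen_best = min(pop, key=lambda ind: ind.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best.copy()
            best_theta = ctx.theta_for(gen_best)
        log_generation(sr)

        controller.update(
            PopulationSummary(
                selection_rate=record.selection_rate[-1], success_rate=sr
            )
        )

    record.best_individual = best
    record.best_theta = best_theta
    return record
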