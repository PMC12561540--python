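"""Genotype decoding and the six feature-threshold control mechanisms.

A real-coded individual x in [0,1]^n becomes a feature subset through the
inclusive threshold rule S = {j : x_j >= theta}. The threshold theta is the
single knob this package studies, controlled by one of:

========  =====================================================================
STATIC    fixed theta (conventionally 0.5)
LR        linear ramp theta_t = theta_min + (t/T)(theta_max - theta_min)
CR        half-cosine ramp theta_t = theta_min + (theta_max-theta_min)/2
          * (1 - cos(pi t / T))
PC        proportional control toward a target selection rate rho*:
          theta_{t+1} = clamp(theta_t + eta (rho_t - rho*))
SRA       success-rate adaptation: multiply theta by c_down=0.85 when the
          population success rate exceeds SR*, by c_up=1.15 otherwise
SA        self-adaptive: each individual carries its own theta gene, varied
          by the optimizer's operators alongside the problem variables
========  =====================================================================

Every controller exposes the same interface: consume a per-generation
population summary, emit the global threshold (or, for SA, delegate to the
individual's own gene).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThresholdBounds",
    "PopulationSummary",
    "ControllerState",
    "ThresholdController",
    "StaticController",
    "LinearScheduleController",
    "CosineScheduleController",
    "ProportionalController",
    "SuccessRateController",
    "SelfAdaptiveController",
    "CONTROLLER_KINDS",
    "make_controller",
    "project",
    "decode_subset",
    "lr_schedule",
    "cr_schedule",
    "pc_update",
    "sra_update",
    "compute_success_rate",
    "compute_selection_rate",
    "sa_init",
    "sa_threshold",
]

CONTROLLER_KINDS = ("STATIC", "LR", "CR", "PC", "SRA", "SA")


@dataclass(frozen=True)
class ThresholdBounds:
    """Admissible threshold interval; defaults 0.1 / 0.9."""

    theta_min: float = 0.1
    theta_max: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_min < self.theta_max < 1.0):
            raise ValueError("need 0 < theta_min < theta_max < 1")


@dataclass(frozen=True)
class PopulationSummary:
    """Per-generation feedback consumed by the adaptive controllers."""

    selection_rate: float  # rho_t: mean fraction of selected features
    success_rate: float  # SR_t: fraction of slots whose fitness improved

    def __post_init__(self) -> None:
        if not (0.0 <= self.selection_rate <= 1.0):
            raise ValueError("selection_rate must lie in [0,1]")
        if not (0.0 <= self.success_rate <= 1.0):
            raise ValueError("success_rate must lie in [0,1]")


@dataclass
class ControllerState:
    """Mutable controller bookkeeping shared by all global mechanisms."""

    kind: str
    theta: float
    bounds: ThresholdBounds = field(default_factory=ThresholdBounds)
    t: int = 0
    horizon: int = 100
    eta: float = 0.05
    rho_star: float = 0.2
    sr_star: float = 0.15
    c_down: float = 0.85
    c_up: float = 1.15


def project(theta: float, bounds: ThresholdBounds) -> float:
    """Clamp theta into [theta_min, theta_max]."""
    return min(max(theta, bounds.theta_min), bounds.theta_max)


def decode_subset(genotype: np.ndarray, theta: float) -> np.ndarray:
    """Inclusive genotype->phenotype decoding: feature j selected iff x_j >= theta."""
    genotype = np.asarray(genotype, dtype=np.float64)
    if not np.all(np.isfinite(genotype)):
        raise ValueError("genotype contains non-finite values")
    if not (0.0 <= theta <= 1.0):
        raise ValueError("theta must lie in [0,1]")
    return genotype >= theta


def _check_schedule_domain(t: int, horizon: int) -> None:
    if horizon < 1:
        raise ValueError("schedule horizon T must be >= 1")
    if not (0 <= t <= horizon):
        raise ValueError(f"generation t={t} outside schedule domain [0, {horizon}]")


def lr_schedule(t: int, horizon: int, bounds: ThresholdBounds) -> float:
    """Linear ramp from theta_min at t=0 to theta_max at t=T."""
    _check_schedule_domain(t, horizon)
    return bounds.theta_min + (t / horizon) * (bounds.theta_max - bounds.theta_min)


def cr_schedule(t: int, horizon: int, bounds: ThresholdBounds) -> float:
    """Half-cosine ramp: slow at both ends, fastest mid-run; same endpoints as LR."""
    _check_schedule_domain(t, horizon)
    return bounds.theta_min + 0.5 * (bounds.theta_max - bounds.theta_min) * (
        1.0 - math.cos(math.pi * t / horizon)
    )


def pc_update(state: ControllerState, selection_rate: float) -> float:
    """One proportional-control step toward the target selection rate.

    A positive error (too many features selected) raises the threshold,
    shrinking the next generation's subsets; a negative error does the
    opposite. Advances the state.
    """
    if not (0.0 <= selection_rate <= 1.0):
        raise ValueError("selection_rate must lie in [0,1]")
    new = project(
        state.theta + state.eta * (selection_rate - state.rho_star), state.bounds
    )
    state.theta = new
    state.t += 1
    return new


def sra_update(state: ControllerState, success_rate: float) -> float:
    """One success-rate-adaptation step.

    Success above target -> multiply by c_down (larger subsets, explore);
    success at or below target -> multiply by c_up (smaller subsets,
    exploit). Advances the state.
    """
    if not (0.0 <= success_rate <= 1.0):
        raise ValueError("success_rate must lie in [0,1]")
    factor = state.c_down if success_rate > state.sr_star else state.c_up
    new = project(state.theta * factor, state.bounds)
    state.theta = new
    state.t += 1
    return new


def compute_success_rate(
    fitness_now: np.ndarray,
    fitness_prev: np.ndarray,
    *,
    literal_increase: bool = False,
) -> float:
    """Fraction of population slots whose fitness improved this generation.

    Fitness is minimized, so improvement means a strict decrease. The
    ``literal_increase`` switch counts strict increases instead, for
    replicating setups that applied the comparison verbatim to a maximized
    score.
    """
    fitness_now = np.asarray(fitness_now, dtype=np.float64)
    fitness_prev = np.asarray(fitness_prev, dtype=np.float64)
    if fitness_now.shape != fitness_prev.shape or fitness_now.ndim != 1:
        raise ValueError("fitness vectors must be 1-D of equal length")
    if fitness_now.size == 0:
        raise ValueError("fitness vectors must be non-empty")
    if literal_increase:
        improved = fitness_now > fitness_prev
    else:
        improved = fitness_now < fitness_prev
    return float(improved.mean())


def compute_selection_rate(genotypes: np.ndarray, theta) -> float:
    """Mean fraction of selected features across the population.

    ``theta`` may be a scalar (global controllers) or a per-individual
    vector (self-adaptive mode).
    """
    genotypes = np.asarray(genotypes, dtype=np.float64)
    if genotypes.ndim != 2 or genotypes.shape[0] == 0:
        raise ValueError("genotypes must be a non-empty (Np, n) matrix")
    theta = np.asarray(theta, dtype=np.float64)
    if theta.ndim == 0:
        thr = np.full(genotypes.shape[0], float(theta))
    else:
        if theta.shape[0] != genotypes.shape[0]:
            raise ValueError("per-individual theta length must match population")
        thr = theta
    fractions = (genotypes >= thr[:, None]).mean(axis=1)
    return float(fractions.mean())


def sa_init(bounds: ThresholdBounds, rng: np.random.Generator) -> float:
    """Draw an individual's initial threshold gene uniformly within bounds."""
    return float(rng.uniform(bounds.theta_min, bounds.theta_max))


def sa_threshold(individual) -> float:
    """Read an individual's own threshold gene (self-adaptive mode only)."""
    theta = getattr(individual, "theta_gene", None)
    if theta is None:
        raise ValueError("individual carries no threshold gene (not in SA mode)")
    return float(theta)


class ThresholdController:
    """Common interface: per-generation feedback in, threshold out."""

    kind: str = "STATIC"
    is_self_adaptive: bool = False

    def __init__(self, bounds: ThresholdBounds | None = None) -> None:
        self.bounds = bounds or ThresholdBounds()
        self.state = ControllerState(kind=self.kind, theta=0.5, bounds=self.bounds)

    @property
    def theta(self) -> float:
        """Current global threshold (undefined for SA, which is per-individual)."""
        return self.state.theta

    def update(self, summary: PopulationSummary) -> None:
        """Advance one generation using the population feedback."""
        self.state.t += 1


class StaticController(ThresholdController):
    """Fixed threshold; the conventional baseline is theta = 0.5."""

    kind = "STATIC"

    def __init__(self, theta: float = 0.5, bounds: ThresholdBounds | None = None):
        super().__init__(bounds)
        if not (0.0 < theta < 1.0):
            raise ValueError("static theta must lie in (0,1)")
        self.state.theta = theta


class _ScheduleController(ThresholdController):
    _schedule = staticmethod(lr_schedule)

    def __init__(self, horizon: int = 100, bounds: ThresholdBounds | None = None):
        super().__init__(bounds)
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        self.state.horizon = horizon
        self.state.theta = self._schedule(0, horizon, self.bounds)

    def update(self, summary: PopulationSummary) -> None:
        # beyond the horizon (budget longer than T generations) hold theta_max
        self.state.t += 1
        t = min(self.state.t, self.state.horizon)
        self.state.theta = self._schedule(t, self.state.horizon, self.bounds)


class LinearScheduleController(_ScheduleController):
    kind = "LR"
    _schedule = staticmethod(lr_schedule)


class CosineScheduleController(_ScheduleController):
    kind = "CR"
    _schedule = staticmethod(cr_schedule)


class ProportionalController(ThresholdController):
    """Feedback control of the selection rate toward a target rho*."""

    kind = "PC"

    def __init__(
        self,
        eta: float = 0.05,
        rho_star: float = 0.2,
        theta0: float = 0.5,
        bounds: ThresholdBounds | None = None,
    ):
        super().__init__(bounds)
        if eta <= 0:
            raise ValueError("learning rate eta must be positive")
        if not (0.0 <= rho_star <= 1.0):
            raise ValueError("target selection rate must lie in [0,1]")
        self.state.eta = eta
        self.state.rho_star = rho_star
        self.state.theta = project(theta0, self.bounds)

    def update(self, summary: PopulationSummary) -> None:
        pc_update(self.state, summary.selection_rate)


class SuccessRateController(ThresholdController):
    """Multiplicative threshold adaptation driven by the population success rate."""

    kind = "SRA"

    def __init__(
        self,
        sr_star: float = 0.15,
        c_down: float = 0.85,
        c_up: float = 1.15,
        theta0: float = 0.5,
        bounds: ThresholdBounds | None = None,
    ):
        super().__init__(bounds)
        if not (0.0 <= sr_star <= 1.0):
            raise ValueError("target success rate must lie in [0,1]")
        self.state.sr_star = sr_star
        self.state.c_down = c_down
        self.state.c_up = c_up
        self.state.theta = project(theta0, self.bounds)

    def update(self, summary: PopulationSummary) -> None:
        sra_update(self.state, summary.success_rate)


class SelfAdaptiveController(ThresholdController):
    """Marker controller: thresholds live in the individuals' genomes."""

    kind = "SA"
    is_self_adaptive = True

    @property
    def theta(self) -> float:
        raise ValueError(
            "SA control has no global threshold; read each individual's gene"
        )


def make_controller(
    kind: str,
    bounds: ThresholdBounds | None = None,
    horizon: int = 100,
    **params,
) -> ThresholdController:
    """Build a controller by kind name; unknown kinds raise."""
    kind = kind.upper()
    if kind == "STATIC":
        return StaticController(bounds=bounds, **params)
    if kind == "LR":
        return LinearScheduleController(horizon=horizon, bounds=bounds)
    if kind == "CR":
        return CosineScheduleController(horizon=horizon, bounds=bounds)
    if kind == "PC":
        return ProportionalController(bounds=bounds, **params)
    if kind == "SRA":
        return SuccessRateController(bounds=bounds, **params)
    if kind == "SA":
        return SelfAdaptiveController(bounds=bounds)
    raise ValueError(f"unknown controller kind {kind!r}; one of {CONTROLLER_KINDS}")
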