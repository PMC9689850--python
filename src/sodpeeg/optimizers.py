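"""Real-valued metaheuristic optimizers: GA, PSO, AsyLnCPSO and the hybrid.

Four population optimizers over real vectors share one driver:

* ``GA`` -- generational genetic algorithm: tournament selection (size 2),
  uniform crossover on a fraction of pairs, per-gene Gaussian mutation with
  a linearly annealed step size, and elitism.
* ``PSO`` -- canonical particle swarm with constant inertia ``w`` and
  learning factors ``c1 = c2``.
* ``AsyLnCPSO`` -- PSO whose cognitive factor ``c1`` decreases linearly
  while the social factor ``c2`` increases linearly over the run
  (asynchronous learning-factor schedule), shifting the swarm from
  exploration towards convergence on the global best.
* ``AsyLnCPSO-GA`` -- the hybrid: each iteration applies the AsyLnCPSO
  velocity/position update and then feeds the whole swarm through the GA
  operators, so recombination can free particles trapped in local optima.

The global best is tracked across operators and, together with GA elitism,
makes the best-so-far trajectory monotone in every mode.  All randomness
flows through one ``numpy`` Generator per run, so identical seed and
configuration reproduce bit-identical trajectories.

The four classical benchmark functions used to validate the optimizers
(Rastrigin, Sphere, Rosenbrock, Schwefel) are included with their standard
search domains; the Schwefel function is the shifted form
``418.9829 d - sum(x sin(sqrt|x|))`` whose global minimum is ~0.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BENCHMARK_DOMAINS",
    "benchmark",
    "SwarmConfig",
    "Swarm",
    "Trajectory",
    "TrialSummary",
    "asylncpso_schedule",
    "pso_step",
    "ga_operate",
    "optimize",
    "run_trials",
]

logger = logging.getLogger(__name__)

MODES = ("GA", "PSO", "AsyLnCPSO", "AsyLnCPSO-GA")

#: Standard per-coordinate search intervals for the benchmark functions.
BENCHMARK_DOMAINS = {
    "rastrigin": (-5.12, 5.12),
    "sphere": (-100.0, 100.0),
    "rosenbrock": (-30.0, 30.0),
    "schwefel": (-500.0, 500.0),
}


def benchmark(name: str, x: Sequence[float]) -> float:
    """Evaluate a standard benchmark function at ``x``.

    All four have global minimum 0: Rastrigin and Sphere at the origin,
    Rosenbrock at the all-ones vector, and the shifted Schwefel at
    ``x_i ~ 420.9687``.
    """
    x = np.asarray(x, dtype=float)
    if name == "rastrigin":
        return float(np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))
    if name == "sphere":
        return float(np.sum(x**2))
    if name == "rosenbrock":
        return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))
    if name == "schwefel":
        return float(418.9829 * x.size - np.sum(x * np.sin(np.sqrt(np.abs(x)))))
    raise ValueError(f"unknown benchmark function {name!r}")


@dataclass(frozen=True)
class SwarmConfig:
    """Configuration shared by all four optimizer modes.

    Bounds are per-coordinate ``(low, high)``; ``v_max`` defaults to 20%
    of the bound width.  ``c1``/``c2`` are the constant learning factors of
    plain PSO; the asynchronous schedule runs ``c1`` from ``c1_start`` down
    to ``c1_end`` and ``c2`` from ``c2_start`` up to ``c2_end``.  GA
    mutation draws per-gene Gaussian steps whose standard deviation anneals
    linearly from ``mutation_sigma_start`` to ``mutation_sigma_end``
    (both as fractions of the bound width) over the run.
    """

    dim: int
    bounds: tuple[float, float]
    pop_size: int = 30
    iterations: int = 200
    trials: int = 20
    w: float = 0.8
    c1: float = 2.0
    c2: float = 2.0
    c1_start: float = 2.5
    c1_end: float = 0.5
    c2_start: float = 0.5
    c2_end: float = 2.5
    v_max: float | None = None
    crossover_rate: float = 0.5
    mutation_rate: float = 0.01
    mutation_sigma_start: float = 0.1
    mutation_sigma_end: float = 0.001
    mode: str = "AsyLnCPSO-GA"
    direction: str = "minimize"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.direction not in ("minimize", "maximize"):
            raise ValueError("direction must be 'minimize' or 'maximize'")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("crossover_rate and mutation_rate must lie in [0, 1]")
        if self.bounds[1] <= self.bounds[0]:
            raise ValueError("bounds must be an increasing (low, high) pair")

    @property
    def range_width(self) -> float:
        return self.bounds[1] - self.bounds[0]

    @property
    def velocity_limit(self) -> float:
        return self.v_max if self.v_max is not None else 0.2 * self.range_width

    def mutation_sigma(self, iteration: int) -> float:
        """Annealed mutation step size (absolute units) at ``iteration``."""
        total = max(self.iterations, 1)
        frac = min(iteration / total, 1.0)
        rel = self.mutation_sigma_start + frac * (self.mutation_sigma_end - self.mutation_sigma_start)
        return rel * self.range_width


@dataclass
class Swarm:
    """Mutable population state: positions, velocities and fitness memory."""

    positions: np.ndarray  # (pop, dim)
    velocities: np.ndarray  # (pop, dim)
    fitness: np.ndarray  # (pop,) internal minimization scale
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float
    n_evaluations: int = 0

    @property
    def pop_size(self) -> int:
        return self.positions.shape[0]

    def refresh_memory(self) -> None:
        """Update per-particle and global bests from current fitness."""
        improved = self.fitness < self.pbest_fitness
        self.pbest_positions[improved] = self.positions[improved]
        self.pbest_fitness[improved] = self.fitness[improved]
        i = int(np.argmin(self.pbest_fitness))
        if self.pbest_fitness[i] < self.gbest_fitness:
            self.gbest_fitness = float(self.pbest_fitness[i])
            self.gbest_position = self.pbest_positions[i].copy()


@dataclass(frozen=True)
class Trajectory:
    """Per-iteration global-best fitness of a single run."""

    gbest_fitness: np.ndarray  # (iterations + 1,) incl. initial population
    gbest_position: np.ndarray
    wall_time_s: float
    n_evaluations: int

    @property
    def final_fitness(self) -> float:
        return float(self.gbest_fitness[-1])


@dataclass(frozen=True)
class TrialSummary:
    """Aggregate over independent seeded trials of one configuration."""

    best_fitness: np.ndarray  # (trials,) final gbest per trial
    best_positions: np.ndarray  # (trials, dim)
    mean_trajectory: np.ndarray
    trajectories: tuple[Trajectory, ...]
    mean_time_s: float

    @property
    def min(self) -> float:
        return float(self.best_fitness.min())

    @property
    def max(self) -> float:
        return float(self.best_fitness.max())

    @property
    def mean(self) -> float:
        return float(self.best_fitness.mean())


def asylncpso_schedule(iteration: int, total: int, config: SwarmConfig) -> tuple[float, float]:
    """Linear asynchronous learning-factor schedule ``(c1_t, c2_t)``.

    Exact at the endpoints: ``t = 0`` gives the start values, ``t = total``
    the end values.
    """
    if total <= 0:
        raise ValueError("total iteration count must be positive")
    frac = iteration / total
    c1 = config.c1_start + frac * (config.c1_end - config.c1_start)
    c2 = config.c2_start + frac * (config.c2_end - config.c2_start)
    return c1, c2


def _evaluate(fn: Callable[[np.ndarray], float], positions: np.ndarray, sign: float) -> np.ndarray:
    """Evaluate positions on the internal minimization scale.

    Non-finite fitness values are treated as worst-possible so the search
    survives degenerate inputs (e.g. empty feature masks).
    """
    vals = np.array([sign * fn(p) for p in positions], dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        logger.warning("replacing %d non-finite fitness values with +inf", int(bad.sum()))
        vals[bad] = np.inf
    return vals


def pso_step(
    swarm: Swarm,
    fn: Callable[[np.ndarray], float],
    config: SwarmConfig,
    rng: np.random.Generator,
    c1: float | None = None,
    c2: float | None = None,
    sign: float = 1.0,
) -> Swarm:
    """One canonical PSO update of every particle, in place.

    ``v <- w v + c1 r1 (pbest - pos) + c2 r2 (gbest - pos)``, velocities
    clamped to ``±v_max``, positions clipped to the bounds, then fitness
    re-evaluated and the best-position memory refreshed.
    """
    c1 = config.c1 if c1 is None else c1
    c2 = config.c2 if c2 is None else c2
    shape = swarm.positions.shape
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    swarm.velocities = (
        config.w * swarm.velocities
        + c1 * r1 * (swarm.pbest_positions - swarm.positions)
        + c2 * r2 * (swarm.gbest_position - swarm.positions)
    )
    vlim = config.velocity_limit
    np.clip(swarm.velocities, -vlim, vlim, out=swarm.velocities)
    swarm.positions = swarm.positions + swarm.velocities
    np.clip(swarm.positions, config.bounds[0], config.bounds[1], out=swarm.positions)
    swarm.fitness = _evaluate(fn, swarm.positions, sign)
    swarm.n_evaluations += swarm.pop_size
    swarm.refresh_memory()
    return swarm


def ga_operate(
    swarm: Swarm,
    fn: Callable[[np.ndarray], float],
    config: SwarmConfig,
    rng: np.random.Generator,
    iteration: int = 0,
    sign: float = 1.0,
) -> Swarm:
    """One GA generation over the swarm positions, in place.

    Tournament selection of size 2 fills the next generation; uniform
    crossover is applied to a ``crossover_rate`` fraction of pairs; every
    gene mutates independently with probability ``mutation_rate`` by a
    Gaussian step of the annealed size.  Only modified individuals are
    re-evaluated, so the extra per-iteration budget is roughly
    ``crossover_rate * pop`` plus the individuals touched by mutation.
    The best individual always survives unchanged (elitism).
    """
    pop, dim = swarm.positions.shape
    elite_idx = int(np.argmin(swarm.fitness))
    elite_pos = swarm.positions[elite_idx].copy()
    elite_fit = float(swarm.fitness[elite_idx])
    elite_vel = swarm.velocities[elite_idx].copy()

    # Tournament selection (size 2): winners carry position, velocity,
    # fitness and their personal-best memory.
    a = rng.integers(pop, size=pop)
    b = rng.integers(pop, size=pop)
    winners = np.where(swarm.fitness[a] <= swarm.fitness[b], a, b)
    positions = swarm.positions[winners].copy()
    velocities = swarm.velocities[winners].copy()
    fitness = swarm.fitness[winners].copy()
    swarm.pbest_positions = swarm.pbest_positions[winners].copy()
    swarm.pbest_fitness = swarm.pbest_fitness[winners].copy()

    modified = np.zeros(pop, dtype=bool)

    # Uniform crossover on the first crossover_rate fraction of random pairs.
    n_pairs = int(round(config.crossover_rate * (pop // 2)))
    if n_pairs > 0:
        order = rng.permutation(pop)
        for k in range(n_pairs):
            i, j = order[2 * k], order[2 * k + 1]
            swap = rng.random(dim) < 0.5
            positions[i, swap], positions[j, swap] = (
                positions[j, swap].copy(),
                positions[i, swap].copy(),
            )
            modified[i] = modified[j] = True

    # Gaussian mutation: every gene mutates independently with probability
    # mutation_rate, by an annealed step size.
    gene_hits = rng.random((pop, dim)) < config.mutation_rate
    if gene_hits.any():
        sigma = config.mutation_sigma(iteration)
        noise = rng.normal(0.0, sigma, size=(pop, dim))
        positions = positions + gene_hits * noise
        np.clip(positions, config.bounds[0], config.bounds[1], out=positions)
        modified |= gene_hits.any(axis=1)

    if modified.any():
        fitness[modified] = _evaluate(fn, positions[modified], sign)
        swarm.n_evaluations += int(modified.sum())

    # Elitism: reinstate the pre-generation best if it was lost.
    if fitness.min() > elite_fit:
        worst = int(np.argmax(fitness))
        positions[worst] = elite_pos
        velocities[worst] = elite_vel
        fitness[worst] = elite_fit

    swarm.positions = positions
    swarm.velocities = velocities
    swarm.fitness = fitness
    swarm.refresh_memory()
    return swarm


def _init_swarm(
    fn: Callable[[np.ndarray], float],
    config: SwarmConfig,
    rng: np.random.Generator,
    sign: float,
) -> Swarm:
    low, high = config.bounds
    positions = rng.uniform(low, high, size=(config.pop_size, config.dim))
    vlim = config.velocity_limit
    velocities = rng.uniform(-vlim, vlim, size=(config.pop_size, config.dim))
    fitness = _evaluate(fn, positions, sign)
    best = int(np.argmin(fitness))
    return Swarm(
        positions=positions,
        velocities=velocities,
        fitness=fitness,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fitness[best]),
        n_evaluations=config.pop_size,
    )


def optimize(
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
    seed: int | np.random.SeedSequence | None = None,
) -> Trajectory:
    """Run one seeded optimization in the configured mode.

    ``fitness`` maps a real vector of length ``config.dim`` to a scalar;
    ``config.direction`` selects minimization or maximization.  The
    returned trajectory records the global best after the initial
    population and after every iteration; elitism plus global-best
    tracking make it monotone.
    """
    sign = 1.0 if config.direction == "minimize" else -1.0
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t0 = time.perf_counter()
    swarm = _init_swarm(fitness, config, rng, sign)
    history = [swarm.gbest_fitness]
    for t in range(config.iterations):
        if config.mode == "GA":
            ga_operate(swarm, fitness, config, rng, iteration=t, sign=sign)
        else:
            if config.mode == "PSO":
                c1, c2 = config.c1, config.c2
            else:
                c1, c2 = asylncpso_schedule(t, config.iterations, config)
            pso_step(swarm, fitness, config, rng, c1=c1, c2=c2, sign=sign)
            if config.mode == "AsyLnCPSO-GA":
                ga_operate(swarm, fitness, config, rng, iteration=t, sign=sign)
        history.append(swarm.gbest_fitness)
    wall = time.perf_counter() - t0
    return Trajectory(
        gbest_fitness=sign * np.asarray(history),
        gbest_position=swarm.gbest_position.copy(),
        wall_time_s=wall,
        n_evaluations=swarm.n_evaluations,
    )


def run_trials(
    fitness: Callable[[np.ndarray], float],
    config: SwarmConfig,
) -> TrialSummary:
    """Repeat :func:`optimize` over independent seeded trials and aggregate.

    Trial seeds are spawned deterministically from ``config.seed``, so two
    configurations sharing a seed see the same per-trial seed stream
    (paired comparisons across modes are meaningful).
    """
    if config.trials < 1:
        raise ValueError("trials must be at least 1")
    children = np.random.SeedSequence(config.seed).spawn(config.trials)
    trajectories = [optimize(fitness, config, seed=child) for child in children]
    best = np.array([t.final_fitness for t in trajectories])
    positions = np.array([t.gbest_position for t in trajectories])
    mean_traj = np.mean([t.gbest_fitness for t in trajectories], axis=0)
    return TrialSummary(
        best_fitness=best,
        best_positions=positions,
        mean_trajectory=mean_traj,
        trajectories=tuple(trajectories),
        mean_time_s=float(np.mean([t.wall_time_s for t in trajectories])),
    )


def benchmark_config(name: str, mode: str, dim: int = 10, seed: int = 0, **kwargs) -> SwarmConfig:
    """Convenience configuration for a benchmark run in standard domains."""
    if name not in BENCHMARK_DOMAINS:
        raise ValueError(f"unknown benchmark function {name!r}")
    return SwarmConfig(dim=dim, bounds=BENCHMARK_DOMAINS[name], mode=mode, seed=seed, **kwargs)
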