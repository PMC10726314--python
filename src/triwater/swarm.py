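"""Bounded particle-swarm optimization of water-model parameters.

A swarm of candidate parameter vectors (d_OH, d_HH, q_O, sigma,
epsilon_lj) explores a box-bounded search space, each particle updated
with the standard velocity rule

    v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

with constriction-style defaults w = 0.72, c1 = c2 = 1.49.  Positions are
clamped to the bounds and the offending velocity component zeroed.  An
optional per-particle self-tuning mode linearly adapts (w, c1, c2) from
two normalized signals - recent fitness improvement and distance to the
global best - as a simplified stand-in for fuzzy self-tuning PSO; the
hyperparameter policy is isolated so a different adaptation can be
swapped in.

Termination is by iteration budget or by swarm collapse: when the maximum
pairwise particle distance, normalized by the bounds extent, falls below
``collapse_radius``, the swarm has effectively agreed on one model.
The optimizer is generic in the evaluator, which must return a finite
fitness everywhere in the box (geometrically invalid vectors should be
penalized, not rejected).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "Particle",
    "SwarmState",
    "OptimizationRun",
    "SolutionEnsemble",
    "initialize",
    "step",
    "optimize",
    "run_ensemble",
    "WATER_PARAM_NAMES",
]

WATER_PARAM_NAMES = ("d_OH", "d_HH", "q_O", "sigma", "epsilon_lj")

DEFAULT_W = 0.72
DEFAULT_C1 = 1.49
DEFAULT_C2 = 1.49


@dataclass(frozen=True)
class SearchSpace:
    """Per-dimension (lower, upper) box bounds."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.ndim != 1:
            raise ValueError("lower and upper must be equal-length 1-D arrays")
        if np.any(lo >= hi):
            raise ValueError("every lower bound must be strictly below its upper bound")
        if self.names is not None and len(self.names) != len(lo):
            raise ValueError("names must match the number of dimensions")

    @property
    def ndim(self) -> int:
        return len(self.lower)

    @property
    def extent(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    fitness: float = np.inf
    # per-particle hyperparameters (mutated only in self-tuning mode)
    w: float = DEFAULT_W
    c1: float = DEFAULT_C1
    c2: float = DEFAULT_C2


@dataclass
class SwarmState:
    particles: list[Particle]
    space: SearchSpace
    rng: np.random.Generator
    iteration: int = 0
    seed: int | None = None
    self_tuning: bool = False

    @property
    def global_best(self) -> tuple[np.ndarray, float]:
        best = min(self.particles, key=lambda p: p.best_fitness)
        return best.best_position.copy(), best.best_fitness

    def spread(self) -> float:
        """Maximum pairwise particle distance, normalized by bounds extent."""
        pos = np.array([p.position for p in self.particles]) / self.space.extent
        diff = pos[:, None, :] - pos[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).max())


@dataclass
class OptimizationRun:
    """History and outcome of a single swarm optimization."""

    best_position: np.ndarray
    best_fitness: float
    best_fitness_history: list[float]
    best_position_history: list[np.ndarray]
    n_iterations: int
    converged: bool
    seed: int | None


@dataclass
class SolutionEnsemble:
    """Final solutions of repeated optimizations under identical settings."""

    positions: np.ndarray  # (n_runs, ndim)
    fitnesses: np.ndarray  # (n_runs,)
    seeds: tuple[int, ...]
    names: tuple[str, ...] | None = None
    runs: list[OptimizationRun] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fitnesses)


def initialize(
    space: SearchSpace,
    n_particles: int,
    seed: int,
    evaluator: Callable[[np.ndarray], float] | None = None,
    self_tuning: bool = False,
) -> SwarmState:
    """Scatter ``n_particles`` uniformly inside the bounds, zero velocities.

    If an evaluator is given, initial fitnesses and personal bests are
    computed immediately; otherwise they stay at +inf until the first step.
    """
    if n_particles < 2:
        raise ValueError("a swarm needs at least 2 particles")
    rng = np.random.default_rng(seed)
    particles = []
    for _ in range(n_particles):
        x = rng.uniform(space.lower, space.upper)
        f = _checked_eval(evaluator, x) if evaluator is not None else np.inf
        particles.append(
            Particle(
                position=x,
                velocity=np.zeros(space.ndim),
                best_position=x.copy(),
                best_fitness=f,
                fitness=f,
            )
        )
    return SwarmState(particles=particles, space=space, rng=rng, seed=seed, self_tuning=self_tuning)


def _checked_eval(evaluator: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    f = float(evaluator(x))
    if not np.isfinite(f):
        raise ValueError(f"evaluator returned non-finite fitness {f} at {x}")
    return f


def step(state: SwarmState, evaluator: Callable[[np.ndarray], float]) -> SwarmState:
    """One synchronous swarm update (in place); returns the state."""
    space = state.space
    gbest, gbest_f = state.global_best
    if not np.isfinite(gbest_f):  # first call without initial evaluation
        for p in state.particles:
            p.fitness = _checked_eval(evaluator, p.position)
            p.best_fitness = p.fitness
            p.best_position = p.position.copy()
        gbest, gbest_f = state.global_best

    extent_norm = float(np.linalg.norm(np.ones(space.ndim)))
    for p in state.particles:
        if state.self_tuning:
            _self_tune(p, gbest, gbest_f, space, extent_norm)
        r1 = state.rng.uniform(size=space.ndim)
        r2 = state.rng.uniform(size=space.ndim)
        p.velocity = (
            p.w * p.velocity
            + p.c1 * r1 * (p.best_position - p.position)
            + p.c2 * r2 * (gbest - p.position)
        )
        new_pos = p.position + p.velocity
        clipped = space.clip(new_pos)
        p.velocity[clipped != new_pos] = 0.0  # kill velocity into the wall
        p.position = clipped
        p.fitness = _checked_eval(evaluator, p.position)
        if p.fitness < p.best_fitness:
            p.best_fitness = p.fitness
            p.best_position = p.position.copy()
    state.iteration += 1
    return state


def _self_tune(
    p: Particle,
    gbest: np.ndarray,
    gbest_f: float,
    space: SearchSpace,
    extent_norm: float,
) -> None:
    """Linear per-particle adaptation of (w, c1, c2).

    Two signals in [0, 1]: delta, the particle's relative excess fitness
    over the global best (0 = at the best), and dist, its normalized
    distance from the global best.  Far/poor particles get higher inertia
    and cognition (explore); close/good particles get higher social pull
    (exploit).
    """
    denom = abs(gbest_f) + 1e-12
    delta = min(max((p.fitness - gbest_f) / denom, 0.0), 1.0)
    dist = float(
        np.linalg.norm((p.position - gbest) / space.extent)
    ) / extent_norm
    dist = min(dist, 1.0)
    p.w = 0.4 + 0.5 * dist
    p.c1 = 1.0 + 1.0 * delta
    p.c2 = 2.0 - 1.0 * delta


def optimize(
    space: SearchSpace,
    evaluator: Callable[[np.ndarray], float],
    n_particles: int = 15,
    max_iter: int = 300,
    seed: int = 0,
    collapse_radius: float = 1e-3,
    self_tuning: bool = False,
) -> OptimizationRun:
    """Run the swarm until collapse or the iteration budget is exhausted."""
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    state = initialize(space, n_particles, seed, evaluator=evaluator, self_tuning=self_tuning)
    best_f_hist: list[float] = []
    best_x_hist: list[np.ndarray] = []
    converged = False
    for _ in range(max_iter):
        step(state, evaluator)
        gbest, gbest_f = state.global_best
        best_f_hist.append(gbest_f)
        best_x_hist.append(gbest)
        if state.spread() < collapse_radius:
            converged = True
            break
    gbest, gbest_f = state.global_best
    return OptimizationRun(
        best_position=gbest,
        best_fitness=gbest_f,
        best_fitness_history=best_f_hist,
        best_position_history=best_x_hist,
        n_iterations=state.iteration,
        converged=converged,
        seed=seed,
    )


def run_ensemble(
    space: SearchSpace,
    evaluator: Callable[[np.ndarray], float],
    n_runs: int,
    seeds: Sequence[int],
    **optimize_kwargs,
) -> SolutionEnsemble:
    """Repeat :func:`optimize` with distinct seeds and collect the solutions."""
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) != n_runs:
        raise ValueError(f"expected {n_runs} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be pairwise distinct")
    runs = [optimize(space, evaluator, seed=s, **optimize_kwargs) for s in seeds]
    return SolutionEnsemble(
        positions=np.array([r.best_position for r in runs]),
        fitnesses=np.array([r.best_fitness for r in runs]),
        seeds=seeds,
        names=space.names,
        runs=runs,
    )
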