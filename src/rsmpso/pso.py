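"""Bound-constrained particle swarm optimization with linear inertia decay.

The swarm follows the classic global-best update.  For particle i,
dimension j, at iteration t:

    V_ij(t+1) = w(t)·V_ij(t) + c1·r1j·(pBest_ij - x_ij) + c2·r2j·(sBest_j - x_ij)
    x_ij(t+1) = x_ij(t) + V_ij(t+1)

with r1j, r2j ~ U[0, 1) drawn per particle, per dimension, per iteration,
and the inertia weight decreased linearly from ``w_start`` to ``w_end``:

    w(k) = w_start - (w_start - w_end)·k / k_max

Positions are initialized uniformly over the bounding box; velocities
are initialized uniformly on (lower - x, upper - x) so a particle's first
move cannot leave the box yet carries enough momentum to cross basins
(zero-velocity initialization lets the swarm collapse onto whichever
local optimum holds the first swarm best on multimodal boxes).
Boundary handling clamps a violating coordinate to the bound and
zeroes that velocity component.  Updates are synchronous: every particle
moves and is evaluated, then personal and swarm bests are refreshed.
Maximization is the native mode; minimization negates the fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "PSOConfig",
    "Particle",
    "Swarm",
    "PSOResult",
    "inertia_at",
    "step_particle",
    "update_bests",
    "optimize",
]


class InvalidPSOConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PSOConfig:
    """Swarm hyper-parameters and the search box.

    ``bounds`` is a sequence of (lower, upper) pairs, one per dimension.
    ``c1`` weights attraction to a particle's own best (cognitive term),
    ``c2`` attraction to the swarm best (social term).
    """

    bounds: tuple[tuple[float, float], ...]
    n_particles: int = 50
    n_iterations: int = 50
    c1: float = 0.5
    c2: float = 0.5
    w_start: float = 1.0
    w_end: float = 0.1
    maximize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "bounds", tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        )
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise InvalidPSOConfigError(f"invalid bound ({lo}, {hi})")
        if self.n_particles < 1 or self.n_iterations < 1:
            raise InvalidPSOConfigError("need >= 1 particle and >= 1 iteration")
        if self.c1 < 0 or self.c2 < 0:
            raise InvalidPSOConfigError("c1 and c2 must be non-negative")
        for w in (self.w_start, self.w_end):
            if not (0.0 < w <= 1.0):
                raise InvalidPSOConfigError("inertia weights must lie in (0, 1]")

    @property
    def n_dim(self) -> int:
        return len(self.bounds)

    @property
    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float


@dataclass
class Swarm:
    particles: list[Particle]
    sbest_position: np.ndarray
    sbest_fitness: float
    trace: list[float] = field(default_factory=list)


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray
    seed: int
    n_evaluations: int


def inertia_at(k: int, config: PSOConfig) -> float:
    """Linearly decayed inertia weight at iteration k (0 <= k <= k_max)."""
    if not 0 <= k <= config.n_iterations:
        raise ValueError(f"iteration {k} outside [0, {config.n_iterations}]")
    return config.w_start - (config.w_start - config.w_end) * k / config.n_iterations


def _clamp(position: np.ndarray, velocity: np.ndarray, config: PSOConfig):
    lo, hi = config.lower, config.upper
    out = (position < lo) | (position > hi)
    position = np.clip(position, lo, hi)
    velocity = np.where(out, 0.0, velocity)
    return position, velocity


def step_particle(
    p: Particle,
    sbest: np.ndarray,
    w: float,
    config: PSOConfig,
    r1: np.ndarray,
    r2: np.ndarray,
) -> Particle:
    """One velocity/position update for a single particle (pure function)."""
    v = (
        w * p.velocity
        + config.c1 * r1 * (p.pbest_position - p.position)
        + config.c2 * r2 * (sbest - p.position)
    )
    x = p.position + v
    x, v = _clamp(x, v, config)
    return Particle(x, v, p.pbest_position.copy(), p.pbest_fitness)


def update_bests(p: Particle, swarm: Swarm, fitness_value: float) -> None:
    """Refresh a particle's personal best and the swarm best in place.

    Improvement is strict (greater fitness in maximization mode; callers
    handle minimization by negating).  Non-finite fitness is rejected.
    """
    if not np.isfinite(fitness_value):
        return
    if fitness_value > p.pbest_fitness:
        p.pbest_fitness = float(fitness_value)
        p.pbest_position = p.position.copy()
        if fitness_value > swarm.sbest_fitness:
            swarm.sbest_fitness = float(fitness_value)
            swarm.sbest_position = p.position.copy()


def optimize(
    fitness: Callable[[np.ndarray], float], config: PSOConfig
) -> PSOResult:
    """Run the full swarm loop; deterministic for a given config and seed."""
    rng = np.random.default_rng(config.seed)
    d = config.n_dim
    sign = 1.0 if config.maximize else -1.0

    def f(x: np.ndarray) -> float:
        return sign * float(fitness(x))

    positions = rng.uniform(config.lower, config.upper, size=(config.n_particles, d))
    velocities = rng.uniform(
        config.lower - positions, config.upper - positions
    )
    particles = []
    n_eval = 0
    for i in range(config.n_particles):
        x = positions[i]
        fit = f(x)
        n_eval += 1
        particles.append(Particle(x.copy(), velocities[i].copy(), x.copy(), fit))
    best = max(particles, key=lambda p: p.pbest_fitness)
    swarm = Swarm(particles, best.pbest_position.copy(), best.pbest_fitness)

    for k in range(1, config.n_iterations + 1):
        w = inertia_at(k, config)
        r1 = rng.random((config.n_particles, d))
        r2 = rng.random((config.n_particles, d))
        # synchronous: move everyone first, then update bests
        moved = [
            step_particle(p, swarm.sbest_position, w, config, r1[i], r2[i])
            for i, p in enumerate(swarm.particles)
        ]
        swarm.particles = moved
        values = [f(p.position) for p in moved]
        n_eval += len(moved)
        for p, val in zip(moved, values):
            update_bests(p, swarm, val)
        swarm.trace.append(sign * swarm.sbest_fitness)

    return PSOResult(
        best_position=swarm.sbest_position.copy(),
        best_fitness=sign * swarm.sbest_fitness,
        trace=np.array(swarm.trace),
        seed=config.seed,
        n_evaluations=n_eval,
    )
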