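"""Optimization of fitted response surfaces over the process box.

Ties the swarm optimizer to fitted surfaces: the fitness function is the
surface prediction at a natural-unit point, and the search box is the
process window (time 4-12 min, amplitude 60-100 %, temperature 40-60 °C
by default).  A dense grid search provides an independent oracle for the
swarm result, and ``evaluate_at`` / ``percent_difference`` support
validating a chosen operating point against confirmatory experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .design import Factor, to_coded
from .pso import PSOConfig, PSOResult, optimize as pso_optimize
from .surfaces import Surface, QuadraticSurface, LinearSurface, predict

__all__ = [
    "DEFAULT_PROCESS_BOUNDS",
    "OptimizationResult",
    "ValidationRecord",
    "optimize_response",
    "grid_search_oracle",
    "evaluate_at",
    "percent_difference",
]

# process window: time (min), amplitude (%), temperature (°C)
DEFAULT_PROCESS_BOUNDS: tuple[tuple[float, float], ...] = (
    (4.0, 12.0),
    (60.0, 100.0),
    (40.0, 60.0),
)

_GRID_LIMIT = 10 ** 8


@dataclass
class OptimizationResult:
    response_name: str
    model_kind: str  # "RSM" | "MLR"
    best_natural: np.ndarray
    best_coded: np.ndarray
    best_predicted: float
    method: str  # "pso" | "grid" | "analytic"
    seed: Optional[int] = None
    trace: Optional[np.ndarray] = None

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "model_kind": self.model_kind,
            "best_natural": list(map(float, self.best_natural)),
            "best_coded": list(map(float, self.best_coded)),
            "best_predicted": float(self.best_predicted),
            "method": self.method,
            "seed": self.seed,
        }


@dataclass
class ValidationRecord:
    """Predicted vs experimentally confirmed response at an operating point."""

    predicted: float
    experimental: float

    @property
    def percent_difference(self) -> float:
        return percent_difference(self.predicted, self.experimental)


def _kind(surface: Surface) -> str:
    return "RSM" if isinstance(surface, QuadraticSurface) else "MLR"


def optimize_response(
    surface: Surface,
    factors: Sequence[Factor],
    bounds: Sequence[tuple[float, float]] = DEFAULT_PROCESS_BOUNDS,
    pso_config: Optional[PSOConfig] = None,
    response_name: str = "",
    seed: int = 0,
) -> OptimizationResult:
    """Maximize a fitted surface over the natural-unit box with PSO.

    The optimizer works directly in natural units; for an affine coding
    the argmax is the same either way and natural units match how
    operating conditions are reported.
    """
    if pso_config is None:
        pso_config = PSOConfig(bounds=tuple(bounds), seed=seed)

    def fitness(x: np.ndarray) -> float:
        return float(predict(surface, x, factors))

    res: PSOResult = pso_optimize(fitness, pso_config)
    best = np.asarray(res.best_position, dtype=float)
    return OptimizationResult(
        response_name=response_name,
        model_kind=_kind(surface),
        best_natural=best,
        best_coded=to_coded(best, factors),
        best_predicted=float(predict(surface, best, factors)),
        method="pso",
        seed=pso_config.seed,
        trace=res.trace,
    )


def grid_search_oracle(
    surface: Surface,
    factors: Sequence[Factor],
    bounds: Sequence[tuple[float, float]] = DEFAULT_PROCESS_BOUNDS,
    points_per_dim: int = 201,
    response_name: str = "",
) -> OptimizationResult:
    """Exhaustive lattice maximization — an independent check on the swarm.

    Evaluates the surface on a regular ``points_per_dim**k`` lattice over
    the box and returns the exact lattice argmax.  Refuses lattices above
    10^8 points.
    """
    if points_per_dim < 2:
        raise ValueError("points_per_dim must be >= 2")
    k = len(bounds)
    if points_per_dim ** k > _GRID_LIMIT:
        raise ValueError(
            f"lattice of {points_per_dim}^{k} points exceeds the {_GRID_LIMIT:g} limit"
        )
    axes = [np.linspace(lo, hi, points_per_dim) for lo, hi in bounds]
    best_val = -np.inf
    best_point: Optional[np.ndarray] = None
    # chunk along the first axis to bound peak memory
    rest = np.stack(
        np.meshgrid(*axes[1:], indexing="ij"), axis=-1
    ).reshape(-1, k - 1)
    for a0 in axes[0]:
        pts = np.column_stack([np.full(rest.shape[0], a0), rest])
        vals = np.asarray(predict(surface, pts, factors))
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val = float(vals[i])
            best_point = pts[i].copy()
    assert best_point is not None
    return OptimizationResult(
        response_name=response_name,
        model_kind=_kind(surface),
        best_natural=best_point,
        best_coded=to_coded(best_point, factors),
        best_predicted=best_val,
        method="grid",
    )


def evaluate_at(
    surface: Surface, factors: Sequence[Factor], natural_point: Sequence[float]
) -> float:
    """Surface prediction at a chosen natural-unit operating point."""
    point = np.asarray(natural_point, dtype=float)
    if not np.all(np.isfinite(point)):
        raise ValueError("operating point must be finite")
    return float(predict(surface, point, factors))


def percent_difference(predicted: float, experimental: float) -> float:
    """100·(predicted - experimental)/predicted.

    The predicted value is the denominator: the question asked is how far
    the confirmatory experiment fell from what the model promised.
    """
    if predicted == 0:
        raise ZeroDivisionError("percent difference undefined for predicted = 0")
    return 100.0 * (predicted - experimental) / predicted
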