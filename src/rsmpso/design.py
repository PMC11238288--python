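"""Central composite designs and natural/coded unit conversion.

A central composite design (CCD) for k factors augments the 2^k factorial
cube (coded levels ±1) with 2k axial points at coded distance ±alpha and
replicated center points.  Factors are stored as a center and a step (the
natural-unit width of one coded unit), so the coded image of a natural
point x is ``(x - center) / step`` and arbitrary off-design query points
remain representable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignPoint",
    "Design",
    "build_ccd",
    "to_coded",
    "to_natural",
]


class InvalidFactorError(ValueError):
    """Raised when a factor or design parameter is ill-formed."""


@dataclass(frozen=True)
class Factor:
    """One controllable process factor.

    Parameters
    ----------
    name:
        Short identifier (e.g. ``"time"``).
    center:
        Natural-unit value at coded 0.
    step:
        Natural units per coded unit; must be positive.
    unit:
        Display unit label (e.g. ``"min"``).
    """

    name: str
    center: float
    step: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise InvalidFactorError(f"factor {self.name!r}: center must be finite")
        if not (np.isfinite(self.step) and self.step > 0):
            raise InvalidFactorError(f"factor {self.name!r}: step must be > 0")


def to_coded(natural: Sequence[float], factors: Sequence[Factor]) -> np.ndarray:
    """Map natural-unit coordinates to coded units, (x - center) / step.

    Accepts a single point of length k or an (n, k) array of points.
    """
    arr = np.asarray(natural, dtype=float)
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (arr - centers) / steps


def to_natural(coded: Sequence[float], factors: Sequence[Factor]) -> np.ndarray:
    """Exact inverse of :func:`to_coded`."""
    arr = np.asarray(coded, dtype=float)
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return centers + steps * arr


@dataclass(frozen=True)
class DesignPoint:
    run_id: int
    coded: tuple[float, ...]
    natural: tuple[float, ...]
    point_class: str  # "factorial" | "axial" | "center"


@dataclass
class Design:
    """A CCD layout: factors plus the ordered list of design points."""

    factors: list[Factor]
    points: list[DesignPoint]
    alpha: float = 2.0

    @property
    def n_runs(self) -> int:
        return len(self.points)

    @property
    def coded_matrix(self) -> np.ndarray:
        return np.array([p.coded for p in self.points], dtype=float)

    @property
    def natural_matrix(self) -> np.ndarray:
        return np.array([p.natural for p in self.points], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: run_id, point_class, natural factors, coded columns."""
        rows = []
        for p in self.points:
            row: dict = {"run_id": p.run_id, "point_class": p.point_class}
            for f, v in zip(self.factors, p.natural):
                row[f.name] = v
            for i, v in enumerate(p.coded, start=1):
                row[f"coded_x{i}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def classify_coded_point(coded: Sequence[float], alpha: float, atol: float = 1e-9) -> str:
    """Classify a coded point as factorial, axial or center; 'other' otherwise."""
    c = np.asarray(coded, dtype=float)
    if np.allclose(c, 0.0, atol=atol):
        return "center"
    if np.allclose(np.abs(c), 1.0, atol=atol):
        return "factorial"
    nonzero = np.abs(c) > atol
    if nonzero.sum() == 1 and np.isclose(np.abs(c[nonzero][0]), alpha, atol=atol):
        return "axial"
    return "other"


def build_ccd(
    factors: Sequence[Factor], alpha: float = 2.0, n_center: int = 6
) -> Design:
    """Build a k-factor central composite design.

    The run order is canonical and deterministic: the 2^k factorial points
    in Yates standard order (first factor alternating fastest), then axial
    pairs (-alpha, +alpha) factor by factor, then the center replicates.

    Parameters
    ----------
    factors:
        The process factors (length k >= 2).
    alpha:
        Axial distance in coded units.  The default of 2 matches a
        five-level design whose axial levels sit two steps from center.
    n_center:
        Number of center replicates (>= 1).
    """
    factors = list(factors)
    k = len(factors)
    if k < 2:
        raise InvalidFactorError("a CCD needs at least 2 factors")
    if not (np.isfinite(alpha) and alpha > 0):
        raise InvalidFactorError("alpha must be > 0")
    if n_center < 1:
        raise InvalidFactorError("n_center must be >= 1")

    coded_points: list[tuple[str, tuple[float, ...]]] = []
    # Yates order: first factor cycles fastest.
    for levels in itertools.product([-1.0, 1.0], repeat=k):
        coded_points.append(("factorial", tuple(reversed(levels))))
    for j in range(k):
        for sign in (-1.0, 1.0):
            c = [0.0] * k
            c[j] = sign * alpha
            coded_points.append(("axial", tuple(c)))
    for _ in range(n_center):
        coded_points.append(("center", (0.0,) * k))

    points = []
    for run_id, (cls, coded) in enumerate(coded_points, start=1):
        natural = tuple(to_natural(coded, factors))
        points.append(DesignPoint(run_id, coded, natural, cls))
    return Design(factors=factors, points=points, alpha=float(alpha))


def design_from_natural(
    natural: np.ndarray, factors: Sequence[Factor], alpha: float = 2.0
) -> Design:
    """Wrap observed natural-unit runs as a Design, recomputing coded columns.

    Coded coordinates are always derived from the factor definitions, never
    trusted from a file, so coding-convention drift cannot occur.
    """
    factors = list(factors)
    natural = np.asarray(natural, dtype=float)
    points = []
    for i, row in enumerate(natural, start=1):
        coded = tuple(to_coded(row, factors))
        points.append(
            DesignPoint(i, coded, tuple(row), classify_coded_point(coded, alpha))
        )
    return Design(factors=factors, points=points, alpha=float(alpha))
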