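"""Model-adequacy statistics over paired experimental/predicted vectors.

Three conventional adequacy measures for comparing regression models on
the same data:

* ``r_squared`` — 1 - SS_res / SS_tot, with SS_tot about the mean of the
  experimental values.
* ``rmse`` — sqrt(mean squared prediction error); the denominator is n,
  the number of pairs, not a degrees-of-freedom correction.
* ``aad_percent`` — absolute average deviation: the mean of
  |predicted - experimental| / |experimental|, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PairedPredictions", "r_squared", "rmse", "aad_percent"]


class UndefinedRSquaredError(ZeroDivisionError):
    pass


@dataclass
class PairedPredictions:
    """Aligned experimental and predicted response vectors."""

    y_experimental: np.ndarray
    y_predicted: np.ndarray

    def __post_init__(self) -> None:
        self.y_experimental = np.asarray(self.y_experimental, dtype=float)
        self.y_predicted = np.asarray(self.y_predicted, dtype=float)
        if self.y_experimental.shape != self.y_predicted.shape:
            raise ValueError("experimental and predicted vectors differ in length")
        if self.y_experimental.ndim != 1 or self.y_experimental.size < 1:
            raise ValueError("need a non-empty 1-D vector of pairs")
        if not (
            np.all(np.isfinite(self.y_experimental))
            and np.all(np.isfinite(self.y_predicted))
        ):
            raise ValueError("non-finite values in paired predictions")

    @property
    def n(self) -> int:
        return self.y_experimental.size


def _as_pairs(pairs, y_predicted=None) -> PairedPredictions:
    if y_predicted is not None:
        return PairedPredictions(pairs, y_predicted)
    return pairs


def r_squared(pairs, y_predicted=None) -> float:
    """Coefficient of determination of predicted vs experimental values."""
    p = _as_pairs(pairs, y_predicted)
    sst = float(np.sum((p.y_experimental - p.y_experimental.mean()) ** 2))
    if sst <= 0:
        raise UndefinedRSquaredError("experimental values have zero variance")
    sse = float(np.sum((p.y_experimental - p.y_predicted) ** 2))
    return 1.0 - sse / sst


def rmse(pairs, y_predicted=None) -> float:
    """Root-mean-square error with denominator n."""
    p = _as_pairs(pairs, y_predicted)
    return float(np.sqrt(np.mean((p.y_predicted - p.y_experimental) ** 2)))


def aad_percent(pairs, y_predicted=None) -> float:
    """Absolute average deviation, percent, normalized by experimental values."""
    p = _as_pairs(pairs, y_predicted)
    zero = np.flatnonzero(p.y_experimental == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"experimental value is zero at index {zero[0]}; AAD undefined"
        )
    return float(
        100.0
        * np.mean(
            np.abs(p.y_predicted - p.y_experimental) / np.abs(p.y_experimental)
        )
    )
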