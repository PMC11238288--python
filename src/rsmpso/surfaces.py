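"""Response-surface (second-order) and multiple-linear-regression models.

Both model families are fitted by ordinary least squares in *coded* units.
Fitting in the coded basis keeps the design matrix well conditioned and
makes the per-term adjusted sums of squares of the ANOVA reproducible;
natural-unit evaluation converts query points through the factor coding.

The full quadratic basis for three factors is, in fixed column order,

    [1, x1, x2, x3, x1^2, x2^2, x3^2, x1*x2, x1*x3, x2*x3]

and the first-order (MLR) basis is ``[1, x1, x2, x3]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .design import Design, Factor, to_coded

__all__ = [
    "ResponseTable",
    "QuadraticSurface",
    "LinearSurface",
    "AnovaReport",
    "build_design_matrix",
    "fit_ols",
    "predict",
    "anova_table",
    "r2_family",
]


class SingularFitError(np.linalg.LinAlgError):
    """Raised when the model matrix is rank deficient."""


class UndefinedRSquaredError(ZeroDivisionError):
    """Raised when the response has zero variance."""


@dataclass
class ResponseTable:
    """A designed experiment with one response: the unit the fitters consume.

    ``y`` holds one response mean per design run; ``replicate_sd`` (the
    run-level replicate standard deviations, when the experiment reports
    them) is carried for display but not used in fitting, which operates
    on run means.
    """

    design: Design
    response_name: str
    y: np.ndarray
    units: str = ""
    replicate_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.design.n_runs,):
            raise ValueError(
                f"y has length {self.y.size}, design has {self.design.n_runs} runs"
            )
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)


SECOND_ORDER_TERMS = (
    "const",
    "x1",
    "x2",
    "x3",
    "x1^2",
    "x2^2",
    "x3^2",
    "x1*x2",
    "x1*x3",
    "x2*x3",
)
FIRST_ORDER_TERMS = ("const", "x1", "x2", "x3")


@dataclass
class QuadraticSurface:
    """Second-order polynomial y = b0 + sum bi xi + sum bii xi^2 + sum bij xi xj.

    Coefficients live in coded units; ``interaction`` is ordered
    (b12, b13, b23).  ``coef_se`` and ``df_resid`` (populated by the
    fitter) carry the OLS standard errors for interval construction.
    """

    b0: float
    linear: np.ndarray  # (b1, b2, b3)
    quadratic: np.ndarray  # (b11, b22, b33)
    interaction: np.ndarray  # (b12, b13, b23)
    basis: str = "coded"
    coef_se: Optional[np.ndarray] = None
    df_resid: Optional[int] = None

    @property
    def coefficients(self) -> np.ndarray:
        """Flat coefficient vector in the fixed second-order column order."""
        return np.concatenate(
            [[self.b0], self.linear, self.quadratic, self.interaction]
        )

    def evaluate_coded(self, coded: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coded, dtype=float))
        x1, x2, x3 = c[:, 0], c[:, 1], c[:, 2]
        b = self.coefficients
        out = (
            b[0]
            + b[1] * x1 + b[2] * x2 + b[3] * x3
            + b[4] * x1 ** 2 + b[5] * x2 ** 2 + b[6] * x3 ** 2
            + b[7] * x1 * x2 + b[8] * x1 * x3 + b[9] * x2 * x3
        )
        return out if np.ndim(coded) > 1 else float(out[0])


@dataclass
class LinearSurface:
    """First-order model y = beta0 + beta1 x1 + beta2 x2 + beta3 x3 (coded)."""

    beta0: float
    betas: np.ndarray
    basis: str = "coded"
    coef_se: Optional[np.ndarray] = None
    df_resid: Optional[int] = None

    @property
    def coefficients(self) -> np.ndarray:
        return np.concatenate([[self.beta0], self.betas])

    def evaluate_coded(self, coded: np.ndarray) -> np.ndarray:
        c = np.atleast_2d(np.asarray(coded, dtype=float))
        out = self.beta0 + c @ self.betas
        return out if np.ndim(coded) > 1 else float(out[0])


Surface = Union[QuadraticSurface, LinearSurface]


def build_design_matrix(design: Design, order: int = 2) -> np.ndarray:
    """Model matrix for the design's coded points, columns in fixed order."""
    return model_matrix_from_coded(design.coded_matrix, order)


def model_matrix_from_coded(coded: np.ndarray, order: int = 2) -> np.ndarray:
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    x1, x2, x3 = coded[:, 0], coded[:, 1], coded[:, 2]
    ones = np.ones_like(x1)
    if order == 1:
        return np.column_stack([ones, x1, x2, x3])
    if order == 2:
        return np.column_stack(
            [ones, x1, x2, x3, x1 ** 2, x2 ** 2, x3 ** 2, x1 * x2, x1 * x3, x2 * x3]
        )
    raise ValueError("order must be 1 or 2")


def fit_ols(table: ResponseTable, order: int = 2) -> Surface:
    """Fit the first- or second-order model by OLS in coded units.

    Raises
    ------
    SingularFitError
        If the model matrix is rank deficient (the coefficients would not
        be identified).
    """
    X = build_design_matrix(table.design, order)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(
            f"model matrix rank {np.linalg.matrix_rank(X)} < {X.shape[1]} columns"
        )
    res = sm.OLS(table.y, X).fit()
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if order == 1:
        return LinearSurface(
            beta0=float(beta[0]), betas=beta[1:4].copy(),
            coef_se=se, df_resid=int(res.df_resid),
        )
    return QuadraticSurface(
        b0=float(beta[0]),
        linear=beta[1:4].copy(),
        quadratic=beta[4:7].copy(),
        interaction=beta[7:10].copy(),
        coef_se=se,
        df_resid=int(res.df_resid),
    )


def predict(
    surface: Surface, natural_point: Sequence[float], factors: Sequence[Factor]
) -> Union[float, np.ndarray]:
    """Evaluate a fitted surface at a natural-unit point (or (n, 3) array)."""
    coded = to_coded(natural_point, factors)
    return surface.evaluate_coded(coded)


def fitted_values(table: ResponseTable, surface: Surface) -> np.ndarray:
    return np.asarray(surface.evaluate_coded(table.design.coded_matrix), dtype=float)


# ---------------------------------------------------------------------------
# ANOVA with lack-of-fit decomposition


@dataclass
class AnovaRow:
    source: str
    df: int
    adj_ss: float
    adj_ms: Optional[float] = None
    f_value: Optional[float] = None
    p_value: Optional[float] = None


@dataclass
class AnovaReport:
    """Per-source adjusted-SS ANOVA for a quadratic response-surface fit.

    Rows follow the conventional layout: model, the linear / square /
    two-way interaction groups with their single-df members, then error
    split into lack-of-fit and pure error, then the corrected total.
    """

    rows: list[AnovaRow]
    r2: float
    adj_r2: float
    pred_r2: float
    response_name: str = ""

    def row(self, source: str) -> AnovaRow:
        for r in self.rows:
            if r.source == source:
                return r
        raise KeyError(source)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": r.source,
                    "df": r.df,
                    "adj_ss": r.adj_ss,
                    "adj_ms": r.adj_ms,
                    "f_value": r.f_value,
                    "p_value": r.p_value,
                }
                for r in self.rows
            ]
        )


# groups of second-order columns by index into the model matrix
_TERM_GROUPS: dict[str, list[int]] = {
    "linear": [1, 2, 3],
    "X1": [1],
    "X2": [2],
    "X3": [3],
    "square": [4, 5, 6],
    "X1^2": [4],
    "X2^2": [5],
    "X3^2": [6],
    "two-way": [7, 8, 9],
    "X1*X2": [7],
    "X1*X3": [8],
    "X2*X3": [9],
}

ANOVA_ROW_ORDER = (
    "model", "linear", "X1", "X2", "X3",
    "square", "X1^2", "X2^2", "X3^2",
    "two-way", "X1*X2", "X1*X3", "X2*X3",
    "error", "lack-of-fit", "pure-error", "total",
)


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df from exact replicate design points."""
    keys = [tuple(np.round(row, 9)) for row in coded]
    ss = 0.0
    df = 0
    for key in set(keys):
        idx = [i for i, k in enumerate(keys) if k == key]
        if len(idx) > 1:
            grp = y[idx]
            ss += float(np.sum((grp - grp.mean()) ** 2))
            df += len(idx) - 1
    return ss, df


def anova_table(table: ResponseTable, surface: QuadraticSurface) -> AnovaReport:
    """Adjusted (type-III) sums of squares ANOVA for the quadratic fit.

    Each term's adjusted SS is the increase in residual SS when that term's
    column(s) are dropped from the otherwise full model; for this orthogonal
    design it coincides with the sequential decomposition.  Residual error
    is split into lack-of-fit (non-replicate structure the model misses)
    and pure error (variability among exact replicate runs); their mean
    square ratio is the lack-of-fit F test.
    """
    if not isinstance(surface, QuadraticSurface):
        raise TypeError("anova_table expects a fitted QuadraticSurface")
    X = build_design_matrix(table.design, order=2)
    y = table.y
    n = y.size

    yhat = fitted_values(table, surface)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    ss_model = sst - sse
    df_model = X.shape[1] - 1
    df_error = n - X.shape[1]
    ms_error = sse / df_error if df_error > 0 else np.nan

    def adj_ss(cols: list[int]) -> float:
        Xr = np.delete(X, cols, axis=1)
        beta, *_ = np.linalg.lstsq(Xr, y, rcond=None)
        return float(np.sum((y - Xr @ beta) ** 2) - sse)

    def f_and_p(ss: float, df: int) -> tuple[Optional[float], Optional[float]]:
        if df_error <= 0 or not np.isfinite(ms_error) or ms_error <= 0:
            return None, None
        f = (ss / df) / ms_error
        return f, float(stats.f.sf(f, df, df_error))

    rows: list[AnovaRow] = []
    f, p = f_and_p(ss_model, df_model)
    rows.append(AnovaRow("model", df_model, ss_model, ss_model / df_model, f, p))
    for name, cols in _TERM_GROUPS.items():
        ss = adj_ss(cols)
        df = len(cols)
        f, p = f_and_p(ss, df)
        rows.append(AnovaRow(name, df, ss, ss / df, f, p))

    ss_pe, df_pe = _pure_error(table.design.coded_matrix, y)
    ss_lof = sse - ss_pe
    df_lof = df_error - df_pe
    rows.append(
        AnovaRow("error", df_error, sse, ms_error if df_error > 0 else None)
    )
    if df_pe > 0 and df_lof > 0:
        ms_lof = ss_lof / df_lof
        ms_pe = ss_pe / df_pe
        f_lof = ms_lof / ms_pe if ms_pe > 0 else None
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe)) if f_lof is not None else None
        rows.append(AnovaRow("lack-of-fit", df_lof, ss_lof, ms_lof, f_lof, p_lof))
        rows.append(AnovaRow("pure-error", df_pe, ss_pe, ms_pe))
    rows.append(AnovaRow("total", n - 1, sst))

    fam = r2_family(table, surface)
    return AnovaReport(
        rows=rows,
        r2=fam["r2"],
        adj_r2=fam["adj_r2"],
        pred_r2=fam["pred_r2"],
        response_name=table.response_name,
    )


def r2_family(table: ResponseTable, surface: Surface) -> dict[str, float]:
    """R², adjusted R² and predicted R² (PRESS-based) for an OLS fit.

    Predicted R² uses the leave-one-out identity ``e_i / (1 - h_ii)`` for
    the deleted residuals, so no refitting is required.
    """
    order = 2 if isinstance(surface, QuadraticSurface) else 1
    X = build_design_matrix(table.design, order)
    y = table.y
    n, p = X.shape
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise UndefinedRSquaredError("response has zero variance; R² undefined")
    resid = y - fitted_values(table, surface)
    sse = float(np.sum(resid ** 2))
    hat = np.einsum("ij,ji->i", X, np.linalg.solve(X.T @ X, X.T))
    press = float(np.sum((resid / (1.0 - hat)) ** 2))
    df_e = n - p
    df_t = n - 1
    return {
        "r2": 1.0 - sse / sst,
        "adj_r2": 1.0 - (sse / df_e) / (sst / df_t) if df_e > 0 else np.nan,
        "pred_r2": 1.0 - press / sst,
    }


def prediction_grid(
    surface: Surface,
    factors: Sequence[Factor],
    bounds: Sequence[tuple[float, float]],
    points_per_dim: int = 25,
) -> pd.DataFrame:
    """Dense natural-unit evaluation grid, e.g. for external 3-D plotting."""
    axes = [np.linspace(lo, hi, points_per_dim) for lo, hi in bounds]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(axes))
    vals = predict(surface, mesh, factors)
    cols = {f.name: mesh[:, i] for i, f in enumerate(factors)}
    cols["predicted"] = np.asarray(vals)
    return pd.DataFrame(cols)
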