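"""Readers, writers and the bundled parsley-juice thermosonication dataset.

The package ships the 20-run central-composite experiment from a
published thermosonication study of parsley juice (time 4–12 min,
amplitude 60–100 %, temperature 40–60 °C; responses total chlorophyll in
mg/100 mL and ascorbic acid in mg/100 g), together with that study's
confirmatory operating point.  ``read_response_table`` ingests any CSV
with the same schema; coded coordinates are always recomputed from the
factor definitions, never trusted from the file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .design import Design, Factor, design_from_natural
from .surfaces import AnovaReport, ResponseTable, Surface, QuadraticSurface, LinearSurface

__all__ = [
    "PROCESS_FACTORS",
    "VALIDATION_POINT",
    "VALIDATION_EXPERIMENTAL",
    "load_parsley_dataset",
    "load_parsley_frame",
    "read_response_table",
    "write_report",
    "render_anova",
    "surface_to_dict",
    "surface_from_dict",
]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


#: Thermosonication process factors: coded unit = one design step.
PROCESS_FACTORS: tuple[Factor, ...] = (
    Factor("time_min", center=8.0, step=2.0, unit="min"),
    Factor("amplitude_pct", center=80.0, step=10.0, unit="%"),
    Factor("temperature_C", center=50.0, step=5.0, unit="°C"),
)

#: Confirmatory operating point chosen in the source study (time, amplitude, temperature).
VALIDATION_POINT: tuple[float, float, float] = (4.4, 88.69, 60.0)

#: Measured responses at the confirmatory point: response -> experimental mean.
VALIDATION_EXPERIMENTAL: dict[str, float] = {
    "chlorophyll": 7.34,
    "ascorbic_acid": 139.23,
}

_RESPONSE_COLUMNS = {
    "chlorophyll": ("chlorophyll_mg_100mL", "chlorophyll_sd", "mg/100 mL"),
    "ascorbic_acid": ("ascorbic_mg_100g", "ascorbic_sd", "mg/100 g"),
}

_FACTOR_COLUMNS = ("time_min", "amplitude_pct", "temperature_C")


def load_parsley_frame() -> pd.DataFrame:
    """The bundled experiment as a raw DataFrame (all printed columns)."""
    with resources.files("rsmpso.data").joinpath(
        "parsley_thermosonication_ccd.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_parsley_dataset(response: str = "chlorophyll") -> ResponseTable:
    """Bundled dataset as a ResponseTable for one response.

    Parameters
    ----------
    response:
        ``"chlorophyll"`` (mg/100 mL) or ``"ascorbic_acid"`` (mg/100 g).
    """
    if response not in _RESPONSE_COLUMNS:
        raise KeyError(
            f"unknown response {response!r}; choose from {sorted(_RESPONSE_COLUMNS)}"
        )
    df = load_parsley_frame()
    ycol, sdcol, units = _RESPONSE_COLUMNS[response]
    design = design_from_natural(
        df[list(_FACTOR_COLUMNS)].to_numpy(float), PROCESS_FACTORS
    )
    return ResponseTable(
        design=design,
        response_name=response,
        y=df[ycol].to_numpy(float),
        units=units,
        replicate_sd=df[sdcol].to_numpy(float),
    )


def read_response_table(
    path: Union[str, Path],
    response_column: str,
    factors: Sequence[Factor] = PROCESS_FACTORS,
    sd_column: Optional[str] = None,
    units: str = "",
) -> ResponseTable:
    """Read a run-per-row CSV into a validated ResponseTable.

    The file must contain ``run_id``, one natural-unit column per factor
    (named as the factors are), and the requested response column.
    """
    df = pd.read_csv(path)
    required = ["run_id", *[f.name for f in factors], response_column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df["run_id"].duplicated().any():
        dup = df.loc[df["run_id"].duplicated(), "run_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate run_id {dup}")
    numeric = [f.name for f in factors] + [response_column]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0])
            raise SchemaError(f"{path}: non-numeric value in column {col!r}, row {row}")
        df[col] = vals
    design = design_from_natural(
        df[[f.name for f in factors]].to_numpy(float), list(factors)
    )
    sd = df[sd_column].to_numpy(float) if sd_column and sd_column in df.columns else None
    return ResponseTable(
        design=design,
        response_name=response_column,
        y=df[response_column].to_numpy(float),
        units=units,
        replicate_sd=sd,
    )


# ---------------------------------------------------------------------------
# serialization


def surface_to_dict(surface: Surface) -> dict:
    if isinstance(surface, QuadraticSurface):
        return {
            "kind": "quadratic",
            "basis": surface.basis,
            "b0": surface.b0,
            "linear": list(map(float, surface.linear)),
            "quadratic": list(map(float, surface.quadratic)),
            "interaction": list(map(float, surface.interaction)),
        }
    return {
        "kind": "linear",
        "basis": surface.basis,
        "beta0": surface.beta0,
        "betas": list(map(float, surface.betas)),
    }


def surface_from_dict(payload: dict) -> Surface:
    if payload["kind"] == "quadratic":
        return QuadraticSurface(
            b0=float(payload["b0"]),
            linear=np.asarray(payload["linear"], dtype=float),
            quadratic=np.asarray(payload["quadratic"], dtype=float),
            interaction=np.asarray(payload["interaction"], dtype=float),
            basis=payload.get("basis", "coded"),
        )
    if payload["kind"] == "linear":
        return LinearSurface(
            beta0=float(payload["beta0"]),
            betas=np.asarray(payload["betas"], dtype=float),
            basis=payload.get("basis", "coded"),
        )
    raise ValueError(f"unknown surface kind {payload['kind']!r}")


def anova_to_dict(report: AnovaReport) -> dict:
    return {
        "response_name": report.response_name,
        "rows": [
            {
                "source": r.source,
                "df": r.df,
                "adj_ss": r.adj_ss,
                "adj_ms": r.adj_ms,
                "f_value": r.f_value,
                "p_value": r.p_value,
            }
            for r in report.rows
        ],
        "r2": report.r2,
        "adj_r2": report.adj_r2,
        "pred_r2": report.pred_r2,
    }


def render_anova(report: AnovaReport) -> str:
    """Aligned text table: source, DF, adj SS, adj MS, F, p, then R² family."""
    lines = [
        f"ANOVA — {report.response_name}",
        f"{'source':<14}{'DF':>4}{'adj SS':>12}{'adj MS':>12}{'F':>10}{'p':>8}",
    ]
    for r in report.rows:
        ms = f"{r.adj_ms:.2f}" if r.adj_ms is not None else ""
        fv = f"{r.f_value:.2f}" if r.f_value is not None else ""
        pv = f"{r.p_value:.3f}" if r.p_value is not None else ""
        lines.append(
            f"{r.source:<14}{r.df:>4}{r.adj_ss:>12.2f}{ms:>12}{fv:>10}{pv:>8}"
        )
    lines.append(f"R2       {100 * report.r2:.2f}%")
    lines.append(f"adj R2   {100 * report.adj_r2:.2f}%")
    lines.append(f"pred R2  {100 * report.pred_r2:.2f}%")
    return "\n".join(lines)


def write_report(payload: dict, path: Union[str, Path]) -> None:
    """Write a JSON report; floats at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default) + "\n")
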