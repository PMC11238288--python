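"""Spectrophotometric and titrimetric assay calculators.

Deterministic converters from raw instrument readings to the bench
quantities used as responses or quality attributes in juice-processing
studies: total chlorophyll from 645/663 nm absorbances, ascorbic acid
from a 2,6-dichloroindophenol (DCPIP) titration, DPPH radical-scavenging
percent inhibition, and total phenolic content against a gallic-acid
calibration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ChlorophyllCoefficients",
    "ChlorophyllReading",
    "TitrationReading",
    "DpphReading",
    "CalibrationCurve",
    "total_chlorophyll",
    "ascorbic_acid",
    "dpph_inhibition",
    "tpc_gae",
    "fit_calibration",
]


@dataclass(frozen=True)
class ChlorophyllCoefficients:
    """Pigment extinction coefficients (mg/L per absorbance unit).

    Defaults are the classic 80 %-acetone coefficients used with the
    Hiscox–Israelstam DMSO extraction protocol:

        chl a  = 12.7·A663 − 2.69·A645
        chl b  = 22.9·A645 − 4.68·A663
        total  = 20.2·A645 + 8.02·A663
    """

    ca_663: float = 12.7
    ca_645: float = 2.69
    cb_645: float = 22.9
    cb_663: float = 4.68
    ct_645: float = 20.2
    ct_663: float = 8.02


@dataclass
class ChlorophyllReading:
    A645: float
    A663: float
    dilution_factor: float = 1.0
    coefficients: ChlorophyllCoefficients = field(
        default_factory=ChlorophyllCoefficients
    )

    def __post_init__(self) -> None:
        if self.A645 < 0 or self.A663 < 0:
            raise ValueError("absorbances must be non-negative")
        if not self.dilution_factor > 0:
            raise ValueError("dilution factor must be positive")


def total_chlorophyll(reading: ChlorophyllReading) -> float:
    """Total chlorophyll in mg per 100 mL of sample.

    Computes chlorophyll a, b and total in mg/L from the two absorbances,
    clips any negative pigment to zero (with a warning), then converts
    mg/L → mg/100 mL and applies the dilution factor.
    """
    c = reading.coefficients
    chl_a = c.ca_663 * reading.A663 - c.ca_645 * reading.A645
    chl_b = c.cb_645 * reading.A645 - c.cb_663 * reading.A663
    total = c.ct_645 * reading.A645 + c.ct_663 * reading.A663
    for name, v in (("chlorophyll a", chl_a), ("chlorophyll b", chl_b), ("total", total)):
        if v < 0:
            warnings.warn(f"negative computed {name} ({v:.4g} mg/L); clipped to 0")
    total = max(total, 0.0)
    return total / 10.0 * reading.dilution_factor  # mg/L -> mg/100 mL


ASCORBIC_ACID_MOLAR_MASS = 176.12  # g/mol


@dataclass
class TitrationReading:
    """DCPIP titration of ascorbic acid.

    MVC: molar mass of ascorbic acid (g/mol); CDPIP: dye concentration
    (mol/L); VDPIP: titrant volume at endpoint (L); VS: titrated sample
    volume (L).
    """

    CDPIP: float
    VDPIP: float
    VS: float
    MVC: float = ASCORBIC_ACID_MOLAR_MASS

    def __post_init__(self) -> None:
        if self.VS <= 0:
            raise ValueError("sample volume VS must be positive")
        if self.CDPIP <= 0 or self.MVC <= 0:
            raise ValueError("MVC and CDPIP must be positive")
        if self.VDPIP < 0:
            raise ValueError("titrant volume cannot be negative")


def ascorbic_acid(
    reading: TitrationReading,
    basis: str = "per_100mL",
    density_g_per_mL: float = 1.0,
) -> float:
    """Ascorbic acid from a DCPIP titration, mg per 100 mL or per 100 g.

    The dye reacts 1:1 with ascorbate, so the titrated mass is
    MVC·CDPIP·VDPIP grams; dividing by the sample volume gives g/L.
    ``basis='per_100g'`` additionally divides by the sample density.
    """
    grams = reading.MVC * reading.CDPIP * reading.VDPIP
    g_per_L = grams / reading.VS
    mg_per_100mL = g_per_L * 100.0  # g/L == mg/mL -> mg/100 mL
    if basis == "per_100mL":
        return mg_per_100mL
    if basis == "per_100g":
        if density_g_per_mL <= 0:
            raise ValueError("density must be positive")
        return mg_per_100mL / density_g_per_mL
    raise ValueError(f"unknown basis {basis!r}")


@dataclass
class DpphReading:
    A0: float  # control absorbance at 517 nm
    A1: float  # sample absorbance

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("control absorbance A0 must be positive")
        if self.A1 < 0:
            raise ValueError("sample absorbance A1 cannot be negative")


def dpph_inhibition(reading: DpphReading) -> float:
    """DPPH radical-scavenging activity, percent: 100·(A0 − A1)/A0."""
    return 100.0 * (reading.A0 - reading.A1) / reading.A0


@dataclass
class CalibrationCurve:
    """Linear standard curve, absorbance = slope·concentration + intercept."""

    slope: float
    intercept: float
    r2: float = float("nan")
    unit_in: str = "absorbance"
    unit_out: str = "mg/L"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope cannot be zero")


def fit_calibration(
    concentrations: Sequence[float], absorbances: Sequence[float]
) -> CalibrationCurve:
    """Least-squares standard curve from >= 2 calibration standards."""
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.size < 2:
        raise ValueError("need at least 2 calibration standards")
    res = stats.linregress(conc, absb)
    return CalibrationCurve(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def tpc_gae(
    absorbance: float, curve: CalibrationCurve, dilution: float = 1.0
) -> float:
    """Total phenolic content as gallic-acid equivalents.

    Inverts the standard curve and scales by the dilution factor; the
    result carries the curve's concentration units (mg GAE/L by default,
    divide by 10 for mg/100 mL).  A reading below the curve intercept
    yields a negative concentration, which is returned with a warning.
    """
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    conc = (absorbance - curve.intercept) / curve.slope * dilution
    if conc < 0:
        warnings.warn(f"absorbance below calibration intercept; TPC {conc:.4g} < 0")
    return conc
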