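"""Reference-method computations for ELSD/HPLC quantitation.

An evaporative light scattering detector responds to analyte mass as a
power law, A = k m^s, so calibration is linear on log-log axes:
log10(A) = s * log10(m) + b. The same exponent links integrated peak
area to sample content (% w/w) because content is proportional to
injected analyte mass at fixed workup; quantitation therefore anchors
on a power law content = c * area^(1/s) fitted to (area, content)
pairs, with an embedded 150-sample determination table as the default
anchor set. Method-validation helpers (RSD, spike recovery, linear
range scaling) round out the reference workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "PeakRecord",
    "PowerLawFit",
    "fit_loglog",
    "fit_power_from_table",
    "content_from_area",
    "table2_fixture",
    "rsd",
    "spike_recovery",
    "linear_range_scale",
    "content_from_mass_chain",
    "round_content",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Log-log standard curve log10(area) = slope*log10(mass mg) + intercept."""

    slope: float
    intercept: float
    r: float
    mass_range: tuple[float, float]


@dataclass(frozen=True)
class PeakRecord:
    """One determination: integrated peak area and content (% w/w, dry basis)."""

    id: str
    area: float
    content: float
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"{self.id}: peak area must be positive")
        if self.content <= 0:
            raise ValueError(f"{self.id}: content must be positive")


@dataclass(frozen=True)
class PowerLawFit:
    """content = c * area^(1/s), fitted on log-log axes."""

    c: float
    s: float
    r_fit: float


def _loglog_ols(lx: np.ndarray, ly: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(lx, ly, 1)
    if np.ptp(ly) == 0 or np.ptp(lx) == 0:
        r = 1.0 if lx.size == 2 else float("nan")
    else:
        r = float(np.corrcoef(lx, ly)[0, 1])
    return float(slope), float(intercept), r


def fit_loglog(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """OLS of log10(area) on log10(injected mass, mg) for a standard series."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (mass, area) points")
    if np.any(pts <= 0):
        raise ValueError("masses and areas must be positive")
    mass, area = pts[:, 0], pts[:, 1]
    slope, intercept, r = _loglog_ols(np.log10(mass), np.log10(area))
    if slope <= 0:
        warnings.warn(
            "non-positive log-log slope: data are outside the power-law model form",
            stacklevel=2,
        )
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        r=1.0 if pts.shape[0] == 2 else r,
        mass_range=(float(mass.min()), float(mass.max())),
    )


def fit_power_from_table(records: Sequence[PeakRecord]) -> PowerLawFit:
    """Fit content = c * area^(1/s) from (area, content) determinations.

    s is the slope of log10(area) on log10(content); c = 10^(-b/s)
    with b the intercept, so that inverting area -> content reproduces
    the fitted line.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    la = np.log10([r.area for r in records])
    lc = np.log10([r.content for r in records])
    if np.ptp(lc) == 0:
        raise ValueError("contents are all equal; power-law fit is degenerate")
    s, b, r = _loglog_ols(lc, la)
    if s <= 0:
        raise ValueError("non-positive exponent: table violates the power-law form")
    return PowerLawFit(c=float(10.0 ** (-b / s)), s=s, r_fit=(1.0 if len(records) == 2 else r))


def round_content(value: float, decimals: int = 4) -> float:
    """Round half-away-from-zero, the convention of printed content tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def content_from_area(area: float, fit: PowerLawFit) -> float:
    """Content (% w/w) from peak area: c * area^(1/s), rounded to 4 decimals."""
    if area <= 0:
        raise ValueError("peak area must be positive")
    return round_content(fit.c * area ** (1.0 / fit.s))


def table2_fixture() -> list[PeakRecord]:
    """The embedded 150-sample determination table (id, area, content, origin)."""
    with resources.files("nirquant.data").joinpath("table2.csv").open() as f:
        df = pd.read_csv(f)
    return [
        PeakRecord(
            id=row["id"],
            area=float(row["peak_area"]),
            content=float(row["content_percent"]),
            origin=row["origin"],
        )
        for _, row in df.iterrows()
    ]


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, percent: 100 * sd(n-1) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(100.0 * v.std(ddof=1) / m)


def spike_recovery(measured_total: float, base: float, spiked: float) -> float:
    """Spike recovery, percent: 100 * (measured_total - base) / spiked."""
    if spiked <= 0:
        raise ValueError("spiked mass must be positive")
    return 100.0 * (measured_total - base) / spiked


def linear_range_scale(mass_low: float, volume_low: float, volume_high: float) -> float:
    """Upper end of the linear range: injected mass scales with volume."""
    if mass_low <= 0 or volume_low <= 0 or volume_high <= 0:
        raise ValueError("masses and volumes must be positive")
    return mass_low * volume_high / volume_low


def content_from_mass_chain(
    mass_per_injection_mg: float,
    extract_volume_ml: float = 50.0,
    injection_volume_ul: float = 20.0,
    sample_mass_g: float = 1.0,
) -> float:
    """Dimensional-chain content: mass per injection scaled to % w/w.

    analyte in extract = mass_per_injection * (extract_volume /
    injection_volume); content = analyte mass / sample mass * 100.
    Exposed for transparency only — the chain's absolute scale is
    inconsistent with determination tables produced under nominally the
    same conditions (a constant factor of roughly 50), so quantitation
    in this package anchors on fit_power_from_table instead.
    """
    analyte_mg = mass_per_injection_mg * (extract_volume_ml * 1000.0 / injection_volume_ul)
    return analyte_mg / (sample_mass_g * 1000.0) * 100.0
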