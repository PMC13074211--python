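"""Per-analyte linear calibration and external-standard quantitation (ESM).

Calibration regresses peak area on on-column amount.  Amounts are expressed
in µg/mL-equivalents at the 10 µL reference injection (amount = standard
concentration × injection volume / 10 µL), the scale on which the shipped
reference regression lines are stated; see docs/methods.md for the unit
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .simulate import REFERENCE_INJECTION_UL

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "EsmResult",
    "LinearityReport",
    "fit_calibration",
    "quantify_esm",
    "check_linearity",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration level: on-column amount and measured area."""

    mass: float  # µg/mL-equivalent amount (concentration × V/10µL)
    area: float  # mAU·s

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be non-negative")


@dataclass
class CalibrationCurve:
    """Fitted line area = slope·amount + intercept with quality metadata."""

    analyte_name: str
    slope: float
    intercept: float
    r: float
    mass_range: tuple[float, float]
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (-1.0 <= self.r <= 1.0 + 1e-12):
            raise ValueError("r must lie in [-1, 1]")
        if self.mass_range[0] > self.mass_range[1]:
            raise ValueError("mass_range must be ordered")

    def predict(self, mass: float) -> float:
        return self.slope * mass + self.intercept

    def invert(self, area: float) -> float:
        """Back-calculate on-column amount from an area."""
        return (area - self.intercept) / self.slope


@dataclass
class EsmResult:
    """External-standard quantitation of one peak."""

    analyte_name: str
    mass: float           # back-calculated amount (clamped at 0)
    concentration: float  # µg/mL in the injected solution
    flags: list[str] = field(default_factory=list)


@dataclass
class LinearityReport:
    analyte_name: str
    passed: bool
    r: float
    threshold: float
    mass_range: tuple[float, float]


def fit_calibration(
    points: Sequence[CalibrationPoint],
    analyte_name: str = "",
    weighting: str = "none",
) -> CalibrationCurve:
    """Fit area = slope·amount + intercept to calibration points.

    Ordinary least squares by default; ``weighting="1/x"`` weights squared
    residuals by the inverse amount (all amounts must then be positive).
    ``r`` is always the plain Pearson correlation of (amount, area).
    Requires at least three points with at least two distinct amounts.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p.mass for p in points], dtype=float)
    y = np.array([p.area for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("calibration is rank deficient: all amounts identical")
    if weighting == "none":
        fit = stats.linregress(x, y)
        slope, intercept, r = float(fit.slope), float(fit.intercept), float(fit.rvalue)
    elif weighting == "1/x":
        if np.any(x <= 0):
            raise ValueError("1/x weighting requires strictly positive amounts")
        w = 1.0 / x
        sw = w.sum()
        mx, my = (w * x).sum() / sw, (w * y).sum() / sw
        slope = float((w * (x - mx) * (y - my)).sum() / (w * (x - mx) ** 2).sum())
        intercept = float(my - slope * mx)
        r = float(stats.pearsonr(x, y).statistic)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CalibrationCurve(
        analyte_name=analyte_name,
        slope=slope,
        intercept=intercept,
        r=min(r, 1.0),
        mass_range=(float(x.min()), float(x.max())),
    )


def quantify_esm(
    area: float,
    curve: CalibrationCurve,
    injection_volume: float = REFERENCE_INJECTION_UL,
) -> EsmResult:
    """Back-calculate concentration from an area via a calibration curve.

    Concentration (µg/mL) = amount × 10 µL / injection volume.  A negative
    back-calculated amount is reported as 0 with a ``below-range`` flag; an
    area outside the calibrated range or below the quantitation/detection
    limits is flagged but still returned.
    """
    if injection_volume <= 0:
        raise ValueError("injection_volume must be positive")
    flags: list[str] = []
    mass = curve.invert(area)
    lo, hi = curve.mass_range
    if not (curve.predict(lo) <= area <= curve.predict(hi)):
        flags.append("outside-calibrated-range")
    if mass < 0:
        mass = 0.0
        flags.append("below-range")
    if curve.lod is not None and mass < curve.lod:
        flags.append("below-lod")
    elif curve.loq is not None and mass < curve.loq:
        flags.append("below-loq")
    concentration = mass * REFERENCE_INJECTION_UL / injection_volume
    return EsmResult(
        analyte_name=curve.analyte_name, mass=mass, concentration=concentration, flags=flags
    )


def check_linearity(curve: CalibrationCurve, r_threshold: float = 0.9990) -> LinearityReport:
    """Pass/fail linearity check on the correlation coefficient."""
    return LinearityReport(
        analyte_name=curve.analyte_name,
        passed=bool(curve.r >= r_threshold),
        r=curve.r,
        threshold=r_threshold,
        mass_range=curve.mass_range,
    )
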