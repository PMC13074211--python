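"""Peak processing: baseline estimation, detection, integration, LOD/LOQ.

Turns raw detector traces into peak tables with the columns
``analyte,t_r_min,area,height,snr``.  Detection is threshold-based on the
baseline-corrected signal; integration is trapezoidal between bounds found
by walking out to a 0.1%-of-height baseline crossing or to the valley
between fused peaks.  Signal-to-noise follows the pharmacopoeial
height/noise convention with the detection limit at S/N = 3 and the
quantitation limit at S/N = 10 (so LOQ/LOD = 10/3 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import Chromatogram, SECONDS_PER_MINUTE

__all__ = [
    "Peak",
    "BaselineEstimate",
    "estimate_baseline",
    "detect_peaks",
    "integrate_peak",
    "estimate_lod_loq",
    "peaks_to_table",
    "read_peak_table",
    "write_peak_table",
]

PEAK_TABLE_COLUMNS = ["analyte", "t_r_min", "area", "height", "snr"]


@dataclass
class Peak:
    """A detected chromatographic peak."""

    t_r: float            # min
    area: float           # mAU·s
    height: float         # mAU
    left_bound: float     # min
    right_bound: float    # min
    snr: float
    analyte_name: str = "unassigned"

    def __post_init__(self) -> None:
        if not (self.left_bound < self.t_r < self.right_bound):
            raise ValueError("peak apex must lie strictly inside its bounds")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("area and height must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class BaselineEstimate:
    """Baseline trace plus a robust white-noise level."""

    baseline: np.ndarray  # mAU, one value per trace point
    noise_sigma: float    # mAU

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def _mad_sigma(x: np.ndarray) -> float:
    if x.size == 0:
        return 0.0
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def estimate_baseline(
    chrom: Chromatogram,
    peak_free_fraction: float = 0.8,
    n_windows: int = 25,
    n_iter: int = 3,
) -> BaselineEstimate:
    """Estimate the baseline and noise level of a trace.

    The baseline is a piecewise-linear interpolation through windowed
    medians of presumed peak-free points; peak points are excluded
    iteratively (everything more than three noise sigmas above the current
    baseline).  ``peak_free_fraction`` is the global signal quantile assumed
    peak-free in the first pass.  The noise level is a
    median-absolute-deviation estimate of the residuals in peak-free
    regions, so a perfectly flat trace yields noise_sigma = 0 and a constant
    baseline.
    """
    if not (0.0 < peak_free_fraction <= 1.0):
        raise ValueError("peak_free_fraction must lie in (0, 1]")
    t, y = chrom.time, chrom.intensity
    if y.size < 100:
        raise ValueError("trace must have at least 100 points")
    cut = np.quantile(y, peak_free_fraction)
    mask = y <= cut
    baseline = np.full_like(y, np.median(y[mask]))
    sigma = 0.0
    edges = np.linspace(0, y.size, n_windows + 1, dtype=int)
    for _ in range(n_iter):
        centers, anchors = [], []
        for lo, hi in zip(edges[:-1], edges[1:]):
            m = mask[lo:hi]
            if m.sum() < max(3, (hi - lo) // 10):
                continue
            centers.append(t[lo:hi][m].mean())
            anchors.append(np.median(y[lo:hi][m]))
        if not centers:  # pathological: everything masked
            break
        baseline = np.interp(t, centers, anchors)
        resid = y - baseline
        sigma = _mad_sigma(resid[mask])
        mask = resid < 3.0 * max(sigma, 1e-12)
    resid = y - baseline
    sigma = _mad_sigma(resid[mask]) if mask.any() else 0.0
    return BaselineEstimate(baseline=baseline, noise_sigma=sigma)


def _walk_bounds(corrected: np.ndarray, apex: int, height: float) -> tuple[int, int]:
    """Find integration bounds: 0.1%-of-height crossing or valley minimum."""
    thr = 1e-3 * height
    left = apex
    while left > 0:
        nxt = corrected[left - 1]
        if nxt <= thr:
            left -= 1
            break
        if nxt > corrected[left] and corrected[left] < 0.5 * height:
            break  # valley between fused peaks
        left -= 1
    right = apex
    last = corrected.size - 1
    while right < last:
        nxt = corrected[right + 1]
        if nxt <= thr:
            right += 1
            break
        if nxt > corrected[right] and corrected[right] < 0.5 * height:
            break
        right += 1
    return left, right


def detect_peaks(
    chrom: Chromatogram,
    baseline: BaselineEstimate,
    min_snr: float = 10.0,
    min_width: float = 0.05,
) -> list[Peak]:
    """Detect local maxima rising at least ``min_snr`` noise sigmas above baseline.

    Returns peaks sorted by retention time; an empty list (not an error)
    when nothing clears the threshold.  Raising ``min_snr`` can only shrink
    the result.
    """
    if min_snr <= 0:
        raise ValueError("min_snr must be positive")
    corrected = chrom.intensity - baseline.baseline
    sigma = baseline.noise_sigma
    if sigma > 0:
        height_thr = min_snr * sigma
    else:  # noiseless trace: any genuinely non-flat excursion counts
        span = float(np.max(corrected, initial=0.0))
        if span <= 0:
            return []
        height_thr = 1e-9 * span
    step = float(chrom.time[1] - chrom.time[0])
    width_pts = max(1, int(round(min_width / step)))
    idx, _ = signal.find_peaks(corrected, height=height_thr, width=width_pts)
    out: list[Peak] = []
    for apex in idx:
        h = float(corrected[apex])
        lo, hi = _walk_bounds(corrected, int(apex), h)
        if hi - lo < 2:
            continue
        area = float(
            np.trapezoid(corrected[lo : hi + 1], chrom.time[lo : hi + 1]) * SECONDS_PER_MINUTE
        )
        if area <= 0:
            continue
        out.append(
            Peak(
                t_r=float(chrom.time[apex]),
                area=area,
                height=h,
                left_bound=float(chrom.time[lo]),
                right_bound=float(chrom.time[hi]),
                snr=h / sigma if sigma > 0 else float("inf"),
            )
        )
    return out


def integrate_peak(
    chrom: Chromatogram, baseline: BaselineEstimate, bounds: tuple[float, float]
) -> float:
    """Trapezoidal integral (mAU·s) of the baseline-corrected signal over ``bounds``.

    Bounds between sample points are handled by linear interpolation of the
    corrected signal, so the integral is exact to trapezoid accuracy rather
    than truncated to the sampling grid.  Clamped at zero; inverted or
    out-of-trace bounds raise.
    """
    left, right = bounds
    if left >= right:
        raise ValueError("bounds must satisfy left < right")
    if left < chrom.time[0] or right > chrom.time[-1]:
        raise ValueError("bounds fall outside the trace")
    corrected = chrom.intensity - baseline.baseline
    lo = int(np.searchsorted(chrom.time, left, side="left"))
    hi = int(np.searchsorted(chrom.time, right, side="right")) - 1
    t_inner = chrom.time[lo : hi + 1]
    y_inner = corrected[lo : hi + 1]
    t = np.concatenate(([left], t_inner, [right]))
    y = np.concatenate(
        (
            [np.interp(left, chrom.time, corrected)],
            y_inner,
            [np.interp(right, chrom.time, corrected)],
        )
    )
    keep = np.concatenate(([True], np.diff(t) > 0))
    area = float(np.trapezoid(y[keep], t[keep]) * SECONDS_PER_MINUTE)
    return max(area, 0.0)


def estimate_lod_loq(noise_sigma: float, height_per_mass: float) -> tuple[float, float]:
    """Detection and quantitation limits from the S/N = 3 and S/N = 10 rules.

    ``height_per_mass`` is the peak height produced per unit on-column
    amount; the returned limits are in that amount unit.  LOQ/LOD is 10/3 by
    construction.
    """
    if height_per_mass <= 0:
        raise ValueError("height_per_mass must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    lod = 3.0 * noise_sigma / height_per_mass
    loq = 10.0 * noise_sigma / height_per_mass
    return lod, loq


def peaks_to_table(peaks: Sequence[Peak]) -> pd.DataFrame:
    """Peak list as a DataFrame with the package's fixed column layout."""
    rows = [
        {
            "analyte": p.analyte_name,
            "t_r_min": p.t_r,
            "area": p.area,
            "height": p.height,
            "snr": p.snr,
        }
        for p in peaks
    ]
    return pd.DataFrame(rows, columns=PEAK_TABLE_COLUMNS)


def write_peak_table(peaks: Sequence[Peak], path: str | Path) -> None:
    peaks_to_table(peaks).to_csv(path, index=False)


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PEAK_TABLE_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    return df
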