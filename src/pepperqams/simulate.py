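"""Synthetic HPLC chromatogram generation with ground-truth annotation.

Every downstream stage of the package (peak processing, calibration,
single-marker quantitation, method comparison) is exercised against traces
produced here, so the generator is first-class, tested code.  It emulates a
reversed-phase HPLC-PDA run of the five analytes of interest — the four
hydroxy-sanshools of Sichuan pepper plus Nonivamide, the stable capsaicin
analogue used as the surrogate reference standard — under a configurable
instrument condition set (instrument, column, flow rate, column temperature,
injection volume, detection wavelength, concentration level).

Peaks are (exponentially modified) Gaussians placed at their nominal
retention times; detector response is linear in on-column amount with a
per-analyte slope/intercept and a per-wavelength relative response factor.
Condition changes act through simple parametric transforms: retention times
scale inversely with flow rate and shift linearly with column temperature,
areas scale with injection volume, concentration level and wavelength
factor, and instrument/column swaps apply one multiplicative time factor
and one area gain shared by all co-injected analytes.  The shared gain is
the mechanism that makes relative correction factors durable: it cancels in
every area ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SECONDS_PER_MINUTE",
    "REFERENCE_INJECTION_UL",
    "ResolutionWarning",
    "ConditionSet",
    "REFERENCE_CONDITION",
    "PeakShapeSpec",
    "NoiseSpec",
    "ResponseModel",
    "AnalyteTruth",
    "GroundTruthManifest",
    "Chromatogram",
    "simulate_chromatogram",
    "simulate_standard_series",
    "simulate_sample_batch",
    "apply_condition_perturbation",
    "simulate_condition_grid",
    "DurabilityRun",
    "content_to_concentration",
]

SECONDS_PER_MINUTE = 60.0
#: Injection volume (µL) at which on-column amount is numerically equal to
#: the standard concentration in µg/mL.  All response slopes refer to this
#: amount scale (see docs/methods.md for the unit convention).
REFERENCE_INJECTION_UL = 10.0


class ResolutionWarning(UserWarning):
    """Two simulated peaks are too close to be resolved cleanly."""


@dataclass(frozen=True)
class ConditionSet:
    """One chromatographic operating point.

    ``conc_level`` is a dimensionless multiplier on all injected
    concentrations, used by the durability protocol's concentration factor.
    """

    instrument_id: str = "LC-20A"
    column_id: str = "SuperLu-C18"
    flow_rate: float = 1.0          # mL/min
    column_temp: float = 35.0       # °C
    injection_volume: float = 10.0  # µL
    wavelength: float = 285.0       # nm
    conc_level: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")
        if self.injection_volume <= 0:
            raise ValueError("injection_volume must be positive")
        if not (190.0 <= self.wavelength <= 800.0):
            raise ValueError("wavelength must lie in [190, 800] nm")
        if self.conc_level <= 0:
            raise ValueError("conc_level must be positive")


REFERENCE_CONDITION = ConditionSet()


@dataclass(frozen=True)
class PeakShapeSpec:
    """Shape and true area of one simulated peak.

    ``tau`` is the exponential tailing constant; 0 gives a pure Gaussian
    centred at ``t_r``.
    """

    analyte_name: str
    t_r: float       # min
    area: float      # mAU·s
    sigma: float = 0.25  # min
    tau: float = 0.0     # min

    def __post_init__(self) -> None:
        if self.t_r <= 0:
            raise ValueError("t_r must be positive")
        if self.area < 0:
            raise ValueError("area must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    def profile(self, t: np.ndarray) -> np.ndarray:
        """Detector trace (mAU) contributed by this peak at times ``t`` (min)."""
        amplitude = self.area / SECONDS_PER_MINUTE  # mAU·min of integrated signal
        if self.tau == 0.0:
            return amplitude * stats.norm.pdf(t, loc=self.t_r, scale=self.sigma)
        k = self.tau / self.sigma
        return amplitude * stats.exponnorm.pdf(t, K=k, loc=self.t_r, scale=self.sigma)


@dataclass(frozen=True)
class NoiseSpec:
    """Stochastic imperfections of a simulated run.

    ``baseline_sigma`` is white detector noise, ``drift_slope`` a linear
    baseline drift.  ``area_rsd`` applies independent multiplicative noise to
    each peak's true area (injection/integration variability) and
    ``rt_jitter_sd`` jitters retention times; both default to 0 so the
    noiseless contracts hold exactly.
    """

    baseline_sigma: float = 0.5   # mAU
    drift_slope: float = 0.0      # mAU/min
    seed: int = 20240101
    area_rsd: float = 0.0         # relative
    rt_jitter_sd: float = 0.0     # min

    def __post_init__(self) -> None:
        if self.baseline_sigma < 0:
            raise ValueError("baseline_sigma must be non-negative")
        if self.area_rsd < 0 or self.rt_jitter_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class ResponseModel:
    """Linear detector response of one analyte.

    ``slope``/``intercept`` define area (mAU·s) as a function of on-column
    amount at the reference wavelength; ``wavelength_factor`` maps detection
    wavelength (nm) to a relative response multiplier applied to the whole
    line (1.0 at the reference wavelength).  ``t_r``/``sigma``/``tau`` carry
    the analyte's nominal peak shape so a full trace can be rendered.
    """

    analyte_name: str
    slope: float                      # mAU·s per amount unit
    intercept: float = 0.0            # mAU·s
    wavelength_factor: Mapping[float, float] = field(default_factory=dict)
    t_r: float = 10.0                 # min
    sigma: float = 0.25               # min
    tau: float = 0.0                  # min
    mass_range: tuple[float, float] | None = None  # declared linear range

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if any(v <= 0 for v in self.wavelength_factor.values()):
            raise ValueError("wavelength_factor values must be positive")

    def factor(self, wavelength: float) -> float:
        """Relative response at ``wavelength``; 1.0 for unmapped channels."""
        if not self.wavelength_factor:
            return 1.0
        key = min(self.wavelength_factor, key=lambda w: abs(w - wavelength))
        return self.wavelength_factor[key] if abs(key - wavelength) <= 2.5 else 1.0

    def area_for(self, mass: float, wavelength: float) -> float:
        """True peak area for on-column amount ``mass`` at ``wavelength``."""
        if mass <= 0:
            return 0.0
        return self.factor(wavelength) * (self.slope * mass + self.intercept)


@dataclass
class AnalyteTruth:
    """Ground truth for one analyte in one simulated run."""

    mass: float                 # on-column amount (µg/mL-equivalent units)
    concentration: float        # µg/mL in the injected solution
    content: float | None = None  # mg/g in the sample, when applicable
    out_of_range: bool = False


@dataclass
class GroundTruthManifest:
    """Per-run truth for a set of simulated chromatograms."""

    records: dict[str, dict[str, AnalyteTruth]] = field(default_factory=dict)
    condition: ConditionSet = REFERENCE_CONDITION
    seed: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition": asdict(self.condition),
            "seed": self.seed,
            "warnings": list(self.warnings),
            "records": {
                run: {name: asdict(tr) for name, tr in entry.items()}
                for run, entry in self.records.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class Chromatogram:
    """A sampled detector trace on one wavelength channel."""

    time: np.ndarray        # min
    intensity: np.ndarray   # mAU
    condition: ConditionSet = REFERENCE_CONDITION
    run_id: str = ""

    @property
    def sampling_rate(self) -> float:
        """Points per minute."""
        return 1.0 / float(self.time[1] - self.time[0])

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write ``time_min,intensity_mau`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"time_min": self.time, "intensity_mau": self.intensity}).to_csv(
            path, index=False
        )
        if sidecar:
            meta = {"run_id": self.run_id, "condition": asdict(self.condition)}
            path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Chromatogram":
        path = Path(path)
        df = pd.read_csv(path)
        condition = REFERENCE_CONDITION
        run_id = path.stem
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            condition = ConditionSet(**meta.get("condition", {}))
            run_id = meta.get("run_id", run_id)
        return cls(
            time=df["time_min"].to_numpy(float),
            intensity=df["intensity_mau"].to_numpy(float),
            condition=condition,
            run_id=run_id,
        )


def simulate_chromatogram(
    peaks: Sequence[PeakShapeSpec],
    duration: float = 50.0,
    sampling_rate: float = 20.0,
    noise: NoiseSpec | None = None,
    condition: ConditionSet | None = None,
    run_id: str = "",
) -> Chromatogram:
    """Render a trace as baseline drift + white noise + sum of peaks.

    Peaks must fit inside ``[0, duration]``; pairs closer than
    3·(sigma_i + sigma_j) emit a :class:`ResolutionWarning`.  With
    ``baseline_sigma = 0`` the numerically integrated area of each isolated
    peak matches its spec area within 0.5% provided sigma spans at least
    five sampling intervals.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate < 10:
        raise ValueError("sampling_rate must be at least 10 points/min")
    noise = noise or NoiseSpec()
    condition = condition or REFERENCE_CONDITION
    for p in peaks:
        if not (0.0 <= p.t_r <= duration):
            raise ValueError(f"peak {p.analyte_name!r} at {p.t_r} min outside run window")
    ordered = sorted(peaks, key=lambda p: p.t_r)
    for a, b in zip(ordered, ordered[1:]):
        if (b.t_r - a.t_r) < 3.0 * (a.sigma + b.sigma):
            warnings.warn(
                f"peaks {a.analyte_name!r} and {b.analyte_name!r} are closer than "
                "3*(sigma_i+sigma_j); integration may merge them",
                ResolutionWarning,
                stacklevel=2,
            )
    step = 1.0 / sampling_rate
    t = np.arange(0.0, duration + step / 2, step)
    rng = np.random.default_rng(noise.seed)
    y = noise.drift_slope * t
    if noise.baseline_sigma > 0:
        y = y + rng.normal(0.0, noise.baseline_sigma, size=t.size)
    for p in peaks:
        if p.area > 0:
            y = y + p.profile(t)
    return Chromatogram(time=t, intensity=y, condition=condition, run_id=run_id)


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _build_peaks(
    masses: Mapping[str, float],
    responses: Mapping[str, ResponseModel],
    condition: ConditionSet,
    rng: np.random.Generator,
    noise: NoiseSpec,
) -> tuple[list[PeakShapeSpec], dict[str, AnalyteTruth], list[str]]:
    """Turn per-analyte on-column amounts into jittered peak specs + truth."""
    peaks: list[PeakShapeSpec] = []
    truth: dict[str, AnalyteTruth] = {}
    notes: list[str] = []
    for name, mass in masses.items():
        if name not in responses:
            raise ValueError(f"no ResponseModel for analyte {name!r}")
        model = responses[name]
        conc = mass * REFERENCE_INJECTION_UL / condition.injection_volume
        out = False
        if model.mass_range is not None and mass > 0:
            lo, hi = model.mass_range
            out = not (lo <= mass <= hi)
            if out:
                notes.append(f"{name}: amount {mass:.4g} outside linear range [{lo}, {hi}]")
        truth[name] = AnalyteTruth(mass=mass, concentration=conc, out_of_range=out)
        area = model.area_for(mass, condition.wavelength)
        if area <= 0:
            continue
        if noise.area_rsd > 0:
            area *= max(rng.normal(1.0, noise.area_rsd), 1e-6)
        t_r = model.t_r
        if noise.rt_jitter_sd > 0:
            t_r += rng.normal(0.0, noise.rt_jitter_sd)
        peaks.append(
            PeakShapeSpec(analyte_name=name, t_r=t_r, area=area, sigma=model.sigma, tau=model.tau)
        )
    return peaks, truth, notes


def simulate_standard_series(
    responses: Mapping[str, ResponseModel],
    levels: Sequence[Mapping[str, float]],
    condition: ConditionSet | None = None,
    noise: NoiseSpec | None = None,
    duration: float = 50.0,
    sampling_rate: float = 20.0,
    run_prefix: str = "std",
) -> tuple[list[Chromatogram], GroundTruthManifest]:
    """Simulate a dilution series of mixed standards.

    Each element of ``levels`` maps analyte name to on-column amount; each
    level yields one chromatogram.  True areas follow each analyte's
    response line scaled by the wavelength factor of the condition's
    channel; amounts outside a declared linear range are flagged in the
    manifest (a warning, not an error).  A zero amount produces no peak.
    """
    condition = condition or REFERENCE_CONDITION
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    manifest = GroundTruthManifest(condition=condition, seed=noise.seed)
    chroms: list[Chromatogram] = []
    for i, masses in enumerate(levels):
        scaled = {k: v * condition.conc_level for k, v in masses.items()}
        run_id = f"{run_prefix}-{i:02d}"
        peaks, truth, notes = _build_peaks(scaled, responses, condition, rng, noise)
        manifest.records[run_id] = truth
        manifest.warnings.extend(f"{run_id}: {n}" for n in notes)
        run_noise = replace(noise, seed=_child_seed(rng))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ResolutionWarning)
            chroms.append(
                simulate_chromatogram(
                    peaks, duration, sampling_rate, run_noise, condition, run_id
                )
            )
    return chroms, manifest


def content_to_concentration(
    content: float, sample_mass: float, extract_volume: float, dilution_k: float = 1.0
) -> float:
    """Invert the content equation: µg/mL in the test solution from mg/g.

    C_i = W_i · M_m / (V · K), converted from mg/mL to µg/mL.
    """
    if sample_mass <= 0 or extract_volume <= 0 or dilution_k <= 0:
        raise ValueError("sample_mass, extract_volume and dilution_k must be positive")
    return content * sample_mass / (extract_volume * dilution_k) * 1000.0


def simulate_sample_batch(
    true_contents: Mapping[str, float],
    responses: Mapping[str, ResponseModel],
    sample_mass: float = 0.025,
    extract_volume: float = 25.0,
    dilution_k: float = 1.0,
    n_replicates: int = 3,
    condition: ConditionSet | None = None,
    noise: NoiseSpec | None = None,
    duration: float = 50.0,
    sampling_rate: float = 20.0,
    sample_id: str = "sample",
) -> tuple[list[Chromatogram], GroundTruthManifest]:
    """Simulate replicate injections of one extracted pepper sample.

    ``true_contents`` maps analyte to mg/g in the dry sample; the content
    equation is inverted to give the test-solution concentration that
    drives peak areas through each analyte's response model.  Replicates
    share the manifest truth but draw independent noise.
    """
    if sample_mass <= 0 or extract_volume <= 0:
        raise ValueError("sample_mass and extract_volume must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    condition = condition or REFERENCE_CONDITION
    noise = noise or NoiseSpec()
    for name in true_contents:
        if name not in responses:
            raise ValueError(f"no ResponseModel for analyte {name!r}")
    rng = np.random.default_rng(noise.seed)
    manifest = GroundTruthManifest(condition=condition, seed=noise.seed)
    chroms: list[Chromatogram] = []
    concs = {
        name: content_to_concentration(w, sample_mass, extract_volume, dilution_k)
        for name, w in true_contents.items()
    }
    masses = {
        name: c * condition.injection_volume / REFERENCE_INJECTION_UL * condition.conc_level
        for name, c in concs.items()
    }
    for rep in range(n_replicates):
        run_id = f"{sample_id}-r{rep + 1}"
        peaks, truth, notes = _build_peaks(masses, responses, condition, rng, noise)
        for name, tr in truth.items():
            tr.content = true_contents[name]
        manifest.records[run_id] = truth
        manifest.warnings.extend(f"{run_id}: {n}" for n in notes)
        run_noise = replace(noise, seed=_child_seed(rng))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ResolutionWarning)
            chroms.append(
                simulate_chromatogram(
                    peaks, duration, sampling_rate, run_noise, condition, run_id
                )
            )
    return chroms, manifest


#: Default multiplicative effects of swapping instrument or column: one
#: retention-time factor and one area gain, shared by every analyte in the
#: run (so area ratios — and hence correction factors — are preserved).
DEFAULT_SYSTEM_EFFECTS: dict[str, float] = {
    "instrument_tr": 1.015,
    "instrument_gain": 1.04,
    "column_tr": 0.96,
    "column_gain": 0.92,
}


def apply_condition_perturbation(
    base_peaks: Sequence[PeakShapeSpec],
    base: ConditionSet,
    new: ConditionSet,
    responses: Mapping[str, ResponseModel] | None = None,
    temp_coefficient: float = -0.05,
    system_effects: Mapping[str, float] | None = None,
) -> list[PeakShapeSpec]:
    """Transform a peak list from one condition set to another.

    Retention times scale as ``base.flow_rate / new.flow_rate``, shift
    linearly with column temperature (``temp_coefficient`` min/°C) and pick
    up a multiplicative factor on instrument/column swaps.  Areas scale with
    injection volume, concentration level, the per-analyte wavelength-factor
    ratio (when ``responses`` is given) and the shared system gain.
    Identical conditions give the identity transformation.
    """
    eff = dict(DEFAULT_SYSTEM_EFFECTS)
    if system_effects:
        eff.update(system_effects)
    t_scale = base.flow_rate / new.flow_rate
    t_shift = temp_coefficient * (new.column_temp - base.column_temp)
    t_factor = 1.0
    gain = (new.injection_volume / base.injection_volume) * (new.conc_level / base.conc_level)
    if new.instrument_id != base.instrument_id:
        t_factor *= eff["instrument_tr"]
        gain *= eff["instrument_gain"]
    if new.column_id != base.column_id:
        t_factor *= eff["column_tr"]
        gain *= eff["column_gain"]
    out: list[PeakShapeSpec] = []
    for p in base_peaks:
        wf = 1.0
        if responses is not None and p.analyte_name in responses:
            model = responses[p.analyte_name]
            wf = model.factor(new.wavelength) / model.factor(base.wavelength)
        out.append(
            replace(
                p,
                t_r=p.t_r * t_scale * t_factor + t_shift,
                area=p.area * gain * wf,
                sigma=p.sigma * t_scale,
            )
        )
    return out


@dataclass
class DurabilityRun:
    """One run of a correction-factor durability grid."""

    condition: ConditionSet
    peak_table: pd.DataFrame          # columns: analyte, t_r_min, area, height, snr
    concentrations: dict[str, float]  # µg/mL, known for every analyte present


def default_durability_grid(base: ConditionSet | None = None) -> list[ConditionSet]:
    """One-factor-at-a-time robustness grid: 16 operating points.

    Two instruments, two columns, four flow rates (0.7/0.9/1.0/1.2 mL/min),
    four column temperatures (25/30/35/40 °C) and four injection volumes
    (5/10/15/20 µL), each varied from the reference point.
    """
    base = base or REFERENCE_CONDITION
    grid: list[ConditionSet] = []
    grid += [replace(base, instrument_id=i) for i in ("LC-20A", "1260")]
    grid += [replace(base, column_id=c) for c in ("SuperLu-C18", "AQ-C18")]
    grid += [replace(base, flow_rate=f) for f in (0.7, 0.9, 1.0, 1.2)]
    grid += [replace(base, column_temp=tc) for tc in (25.0, 30.0, 35.0, 40.0)]
    grid += [replace(base, injection_volume=v) for v in (5.0, 10.0, 15.0, 20.0)]
    return grid


def simulate_condition_grid(
    responses: Mapping[str, ResponseModel],
    concentrations: Mapping[str, float],
    grid: Sequence[ConditionSet] | None = None,
    base: ConditionSet | None = None,
    noise: NoiseSpec | None = None,
    run_gain_rsd: float = 0.0,
) -> list[DurabilityRun]:
    """Simulate ground-truth peak tables of one standard mix across a grid.

    ``run_gain_rsd`` draws one multiplicative gain per run shared by all
    analytes (detector sensitivity differences between runs); ``noise.area_rsd``
    adds independent per-peak noise on top.  The shared gain cancels in every
    correction-factor ratio, which is what the durability assessment verifies.
    """
    base = base or REFERENCE_CONDITION
    grid = list(grid) if grid is not None else default_durability_grid(base)
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(noise.seed)
    base_peaks = []
    for name, conc in concentrations.items():
        if name not in responses:
            raise ValueError(f"no ResponseModel for analyte {name!r}")
        model = responses[name]
        mass = conc * base.injection_volume / REFERENCE_INJECTION_UL
        area = model.area_for(mass, base.wavelength)
        if area > 0:
            base_peaks.append(
                PeakShapeSpec(name, model.t_r, area, sigma=model.sigma, tau=model.tau)
            )
    runs: list[DurabilityRun] = []
    for i, cond in enumerate(grid):
        peaks = apply_condition_perturbation(base_peaks, base, cond, responses=responses)
        gain = max(rng.normal(1.0, run_gain_rsd), 1e-6) if run_gain_rsd > 0 else 1.0
        rows = []
        for p in peaks:
            area = p.area * gain
            if noise.area_rsd > 0:
                area *= max(rng.normal(1.0, noise.area_rsd), 1e-6)
            height = area / SECONDS_PER_MINUTE / (p.sigma * math.sqrt(2.0 * math.pi))
            rows.append(
                {"analyte": p.analyte_name, "t_r_min": p.t_r, "area": area,
                 "height": height, "snr": np.inf}
            )
        concs = {
            name: c * cond.conc_level for name, c in concentrations.items()
        }
        runs.append(
            DurabilityRun(condition=cond, peak_table=pd.DataFrame(rows), concentrations=concs)
        )
    return runs
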