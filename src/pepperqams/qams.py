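"""Single-marker quantitation core: correction factors, RRT assignment, content.

The QAMS idea: calibrate one cheap, stable marker (here Nonivamide, or
hydroxy-α-sanshool) and quantify every other analyte through a fixed
relative correction factor

    f_is = (A_s · C_i) / (A_i · C_s)

measured once on mixed standards, so that an unknown's concentration is

    C_i = f_is · C_s · A_i / A_s .

The two relations are algebraic inverses, so quantifying the calibration
mix with its own correction factors recovers the known concentrations
exactly.  Peaks are identified across instruments and columns by relative
retention time RRT = t_i / t_s, which is invariant under the common
rescaling of all retention times that a flow-rate change produces.
Durability of f across deliberate condition changes is summarised as the
RSD of the per-condition factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .simulate import ConditionSet, DurabilityRun
from .peaks import Peak

__all__ = [
    "AnalyteDef",
    "MethodConfig",
    "RCFEstimate",
    "QuantResult",
    "AssignmentResult",
    "compute_rcf",
    "quantify_qams",
    "compute_rrt",
    "compute_content",
    "assign_peaks",
    "assess_rcf_durability",
]


@dataclass(frozen=True)
class AnalyteDef:
    """One analyte of a QAMS method: expected RRT and correction factor."""

    name: str
    expected_rrt: float
    rcf: float
    is_internal_reference: bool = False

    def __post_init__(self) -> None:
        if self.expected_rrt <= 0 or self.rcf <= 0:
            raise ValueError("expected_rrt and rcf must be positive")
        if self.is_internal_reference and abs(self.expected_rrt - 1.0) > 1e-9:
            raise ValueError("the internal reference must have expected_rrt = 1")


@dataclass
class MethodConfig:
    """A complete single-marker method: analytes, IR, channel, tolerances."""

    name: str
    analytes: list[AnalyteDef]
    wavelength: float
    rrt_tolerance: float = 0.05
    ir_locator: tuple[str, float | None] = ("nearest-time", None)
    ir_standard_conc: float | None = None  # µg/mL of the marker standard
    durability_threshold: float = 3.0      # % RSD

    def __post_init__(self) -> None:
        irs = [a for a in self.analytes if a.is_internal_reference]
        if len(irs) != 1:
            raise ValueError("exactly one analyte must be the internal reference")

    @property
    def ir(self) -> AnalyteDef:
        return next(a for a in self.analytes if a.is_internal_reference)

    def rcf_of(self, name: str) -> float:
        for a in self.analytes:
            if a.name == name:
                return a.rcf
        raise KeyError(name)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "wavelength": self.wavelength,
            "rrt_tolerance": self.rrt_tolerance,
            "ir_locator": list(self.ir_locator),
            "ir_standard_conc": self.ir_standard_conc,
            "durability_threshold": self.durability_threshold,
            "analytes": [
                {
                    "name": a.name,
                    "expected_rrt": a.expected_rrt,
                    "rcf": a.rcf,
                    "is_internal_reference": a.is_internal_reference,
                }
                for a in self.analytes
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MethodConfig":
        raw = yaml.safe_load(Path(path).read_text())
        analytes = [AnalyteDef(**a) for a in raw.pop("analytes")]
        locator = raw.pop("ir_locator", ["nearest-time", None])
        return cls(analytes=analytes, ir_locator=(locator[0], locator[1]), **raw)


@dataclass
class RCFEstimate:
    """Per-condition correction factors of one analyte, with durability stats."""

    analyte_name: str
    ir_name: str
    per_condition_f: dict[ConditionSet, float]
    mean_f: float
    rsd_percent: float
    durable: bool

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.per_condition_f.values()):
            raise ValueError("all correction factors must be positive")
        if self.rsd_percent < 0:
            raise ValueError("rsd_percent must be non-negative")


@dataclass
class QuantResult:
    """Concentration and content of one analyte by one method."""

    analyte_name: str
    method: str                 # "ESM" or "QAMS"
    c_i: float                  # µg/mL
    w_i: float                  # mg/g
    ir_name: str | None = None
    sample_id: str = ""
    replicate: int = 1
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.c_i < 0 or self.w_i < 0:
            raise ValueError("c_i and w_i must be non-negative")


@dataclass
class AssignmentResult:
    """Outcome of RRT-based peak assignment."""

    assigned: dict[str, Peak]
    missing: list[str]
    ir_name: str


def compute_rcf(c_s: float, a_s: float, c_i: float, a_i: float) -> float:
    """Relative correction factor f_is = (A_s · C_i) / (A_i · C_s)."""
    if min(c_s, a_s, c_i, a_i) <= 0:
        raise ValueError("all concentrations and areas must be positive")
    return (a_s * c_i) / (a_i * c_s)


def quantify_qams(a_i: float, a_s: float, c_s: float, f: float) -> float:
    """Analyte concentration C_i = f · C_s · A_i / A_s."""
    if a_s <= 0:
        raise ValueError("internal-reference area must be positive")
    if c_s <= 0 or f <= 0:
        raise ValueError("c_s and f must be positive")
    if a_i < 0:
        raise ValueError("a_i must be non-negative")
    return f * c_s * a_i / a_s


def compute_rrt(t_r_x: float, t_r_s: float) -> float:
    """Relative retention time t_x / t_s."""
    if t_r_x <= 0 or t_r_s <= 0:
        raise ValueError("retention times must be positive")
    return t_r_x / t_r_s


def compute_content(c_i: float, v: float, k: float, m_m: float) -> float:
    """Mass content W_i (mg/g) = C_i (mg/mL) · V (mL) · K / M_m (g)."""
    if v <= 0:
        raise ValueError("extract volume must be positive")
    if k < 1:
        raise ValueError("dilution factor must be at least 1")
    if m_m <= 0:
        raise ValueError("sample mass must be positive")
    if c_i < 0:
        raise ValueError("concentration must be non-negative")
    return c_i * v * k / m_m


def _locate_ir(
    peaks: Sequence[Peak], strategy: tuple[str, float | None], ir_name: str
) -> Peak:
    kind, param = strategy
    if kind == "tallest":
        return max(peaks, key=lambda p: p.height)
    if kind == "nearest-time":
        if param is None:
            raise ValueError("nearest-time locator needs a retention time")
        return min(peaks, key=lambda p: abs(p.t_r - param))
    if kind == "labeled":
        for p in peaks:
            if p.analyte_name == ir_name:
                return p
        raise ValueError(f"no peak labeled {ir_name!r} in the table")
    raise ValueError(f"unknown IR locator strategy {kind!r}")


def assign_peaks(
    peaks: Sequence[Peak],
    analytes: Sequence[AnalyteDef],
    rrt_tolerance: float = 0.05,
    ir_locator: tuple[str, float | None] = ("tallest", None),
) -> AssignmentResult:
    """Match peaks to analytes by relative retention time.

    The internal reference is located first by the configured strategy; each
    remaining analyte is matched to the unassigned peak whose RRT is nearest
    its expectation and within the relative tolerance.  When two analytes
    claim the same peak the smaller relative deviation wins and the loser is
    reported missing (no cascading).  Unmatched analytes appear in
    ``missing``; an unlocatable IR is an error.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    irs = [a for a in analytes if a.is_internal_reference]
    if len(irs) != 1:
        raise ValueError("exactly one analyte must be the internal reference")
    ir = irs[0]
    ir_peak = _locate_ir(peaks, ir_locator, ir.name)
    assigned: dict[str, Peak] = {ir.name: ir_peak}
    # Each analyte's single best candidate among non-IR peaks.
    claims: list[tuple[float, str, Peak]] = []
    missing: list[str] = []
    for a in analytes:
        if a.is_internal_reference:
            continue
        best: tuple[float, Peak] | None = None
        for p in peaks:
            if p is ir_peak:
                continue
            rel_err = abs(compute_rrt(p.t_r, ir_peak.t_r) - a.expected_rrt) / a.expected_rrt
            if rel_err <= rrt_tolerance and (best is None or rel_err < best[0]):
                best = (rel_err, p)
        if best is None:
            missing.append(a.name)
        else:
            claims.append((best[0], a.name, best[1]))
    taken: set[int] = set()
    for rel_err, name, peak in sorted(claims, key=lambda c: c[0]):
        if id(peak) in taken:
            missing.append(name)  # tie lost to a closer analyte
            continue
        taken.add(id(peak))
        assigned[name] = peak
    return AssignmentResult(assigned=assigned, missing=missing, ir_name=ir.name)


def assess_rcf_durability(
    runs: Sequence[DurabilityRun],
    ir_name: str,
    durability_threshold: float = 3.0,
) -> list[RCFEstimate]:
    """Correction factors per condition, with mean, RSD and a durability flag.

    Every run's peak table must contain the internal reference (by analyte
    label) and known concentrations for each analyte evaluated.  RSD is
    100·std/mean over conditions (sample std); a single condition gives
    RSD = 0.  Analytes whose RSD exceeds ``durability_threshold`` (percent)
    are flagged as not durable.
    """
    if not runs:
        raise ValueError("no durability runs given")
    per_analyte: dict[str, dict[ConditionSet, float]] = {}
    for i, run in enumerate(runs):
        table = run.peak_table
        ir_rows = table[table["analyte"] == ir_name]
        if ir_rows.empty:
            raise ValueError(
                f"internal reference {ir_name!r} missing from run {i} "
                f"({run.condition.instrument_id}/{run.condition.column_id})"
            )
        if ir_name not in run.concentrations:
            raise ValueError(f"no known concentration for {ir_name!r} in run {i}")
        a_s = float(ir_rows["area"].iloc[0])
        c_s = float(run.concentrations[ir_name])
        for _, row in table.iterrows():
            name = row["analyte"]
            if name == ir_name or name not in run.concentrations:
                continue
            f = compute_rcf(c_s, a_s, float(run.concentrations[name]), float(row["area"]))
            per_analyte.setdefault(name, {})[run.condition] = f
    out: list[RCFEstimate] = []
    for name, fs in per_analyte.items():
        values = np.array(list(fs.values()), dtype=float)
        mean = float(values.mean())
        rsd = float(100.0 * values.std(ddof=1) / mean) if values.size > 1 else 0.0
        out.append(
            RCFEstimate(
                analyte_name=name,
                ir_name=ir_name,
                per_condition_f=fs,
                mean_f=mean,
                rsd_percent=rsd,
                durable=rsd <= durability_threshold,
            )
        )
    out.sort(key=lambda e: e.analyte_name)
    return out
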