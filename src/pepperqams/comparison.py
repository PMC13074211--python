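"""Method-equivalence and validation statistics.

The equivalence criterion between the external-standard method and the
single-marker method is the standardized mean difference

    SMD% = |W_ref − W_alt| / W_ref × 100 ,

accepted when strictly below 5%.  Note the denominator is the first
(reference) method, so SMD is deliberately asymmetric.  The same formula
compares the two internal-standard choices against each other.  Validation
summaries (precision, stability, repeatability as RSDs; spiked recovery)
follow the usual analytical conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .qams import QuantResult

__all__ = [
    "ComparisonReport",
    "ValidationSummary",
    "compute_smd",
    "compare_methods",
    "summarize_validation",
    "batch_report",
]

DEFAULT_SMD_THRESHOLD = 5.0  # percent


@dataclass
class ComparisonReport:
    """Per-sample, per-analyte SMD between two methods."""

    method_a: str
    method_b: str
    table: pd.DataFrame  # sample_id, analyte, w_a, w_b, smd_percent, passed
    threshold: float
    overall_pass: bool

    @property
    def max_smd(self) -> float:
        return float(self.table["smd_percent"].max())

    def per_analyte_max(self) -> pd.Series:
        return self.table.groupby("analyte")["smd_percent"].max()


@dataclass
class ValidationSummary:
    """RSDs per analyte for one validation aspect, plus optional recovery."""

    label: str
    rsd_percent: dict[str, float]
    recovery_percent: dict[str, float] = field(default_factory=dict)
    recovery_rsd_percent: dict[str, float] = field(default_factory=dict)


def compute_smd(w_ref: float, w_alt: float) -> float:
    """Standardized mean difference |w_ref − w_alt| / w_ref × 100 (percent)."""
    if w_ref <= 0:
        raise ValueError("reference content must be positive (denominator)")
    if w_alt < 0:
        raise ValueError("alternative content must be non-negative")
    return abs(w_ref - w_alt) / w_ref * 100.0


def _mean_contents(results: Sequence[QuantResult]) -> dict[tuple[str, str], float]:
    acc: dict[tuple[str, str], list[float]] = {}
    for r in results:
        acc.setdefault((r.sample_id, r.analyte_name), []).append(r.w_i)
    return {k: float(np.mean(v)) for k, v in acc.items()}


def compare_methods(
    results_a: Sequence[QuantResult],
    results_b: Sequence[QuantResult],
    threshold: float = DEFAULT_SMD_THRESHOLD,
) -> ComparisonReport:
    """SMD per (sample, analyte) between two result sets.

    Replicates are averaged per key before the SMD is taken (the "mean of
    parallel determinations" convention); the first argument supplies the
    SMD denominator.  Keys present in one set but not the other raise.
    """
    if not results_a or not results_b:
        raise ValueError("nothing to compare: empty result set")
    wa = _mean_contents(results_a)
    wb = _mean_contents(results_b)
    if set(wa) != set(wb):
        odd = sorted(set(wa).symmetric_difference(set(wb)))
        raise ValueError(f"unmatched (sample, analyte) keys: {odd}")
    rows = []
    for key in sorted(wa):
        smd = compute_smd(wa[key], wb[key])
        rows.append(
            {
                "sample_id": key[0],
                "analyte": key[1],
                "w_a": wa[key],
                "w_b": wb[key],
                "smd_percent": smd,
                "passed": smd < threshold,
            }
        )
    table = pd.DataFrame(rows)
    label_a = results_a[0].method + (f"[{results_a[0].ir_name}]" if results_a[0].ir_name else "")
    label_b = results_b[0].method + (f"[{results_b[0].ir_name}]" if results_b[0].ir_name else "")
    return ComparisonReport(
        method_a=label_a,
        method_b=label_b,
        table=table,
        threshold=threshold,
        overall_pass=bool(table["passed"].all()),
    )


def summarize_validation(
    replicates: Mapping[str, Sequence[float]],
    spiked: Mapping[str, tuple[float, float, Sequence[float]]] | None = None,
    label: str = "precision",
) -> ValidationSummary:
    """RSD per analyte over replicate determinations, plus spiked recovery.

    ``replicates`` maps analyte to ≥ 2 repeated values (singletons raise).
    ``spiked`` maps analyte to (measured_base, added, spiked_measurements);
    recovery = (spiked − base) / added × 100, reported as mean and RSD over
    the spiked measurements.
    """
    rsd: dict[str, float] = {}
    for name, values in replicates.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"analyte {name!r}: need at least 2 replicates")
        mean = arr.mean()
        rsd[name] = float(100.0 * arr.std(ddof=1) / mean) if mean != 0 else 0.0
    recovery: dict[str, float] = {}
    recovery_rsd: dict[str, float] = {}
    if spiked:
        for name, (base, added, measured) in spiked.items():
            if added <= 0:
                raise ValueError(f"analyte {name!r}: spiked amount must be positive")
            rec = 100.0 * (np.asarray(measured, dtype=float) - base) / added
            recovery[name] = float(rec.mean())
            recovery_rsd[name] = (
                float(100.0 * rec.std(ddof=1) / rec.mean()) if rec.size > 1 else 0.0
            )
    return ValidationSummary(
        label=label,
        rsd_percent=rsd,
        recovery_percent=recovery,
        recovery_rsd_percent=recovery_rsd,
    )


def batch_report(results: Sequence[QuantResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format table plus per-analyte min/max/mean ± sd summary.

    Results are grouped by method (never pooled across methods).  The sd is
    computed across replicates within each sample; the range and mean are
    taken across sample means.
    """
    if not results:
        raise ValueError("no results to report")
    long = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "analyte": r.analyte_name,
                "method": r.method,
                "ir_name": r.ir_name or "",
                "replicate": r.replicate,
                "c_i_ug_ml": r.c_i,
                "w_i_mg_g": r.w_i,
            }
            for r in results
        ]
    )
    per_sample = (
        long.groupby(["method", "ir_name", "analyte", "sample_id"])["w_i_mg_g"]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary = (
        per_sample.groupby(["method", "ir_name", "analyte"])
        .agg(
            w_min=("mean", "min"),
            w_max=("mean", "max"),
            w_mean=("mean", "mean"),
            replicate_sd=("std", "mean"),
            n_samples=("mean", "size"),
        )
        .reset_index()
    )
    return long, summary
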