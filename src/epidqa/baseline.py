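"""Benchmark persistence and daily pass/fail evaluation.

The workflow: with the LINAC in its best state, one open + one wedge
acquisition defines the benchmark metric set, stored as a human-diffable
JSON document per machine + beam and valid for one year.  Each working day
the same acquisition is repeated and compared against the benchmark:

* output and beam quality (wedge factor) as ratio deviations, expressed as
  percent-from-100 (daily / baseline * 100 - 100);
* flatness and symmetry as absolute percentage-point differences;
* field size and field center as mm differences.

A parameter fails when its |deviation| exceeds its tolerance.  The default
output tolerance is +-2.5 % — tighter than the generic 3 % daily output
bound, compensating for the slightly larger shot-to-shot fluctuation of a
flat-panel ROI mean compared with an ion chamber.  The remaining defaults
(BQ 2 %, F/S 2 points, size 2 mm, center 2 mm) are explicit, overridable
choices in the spirit of TG-142 daily tests.  A run past the baseline's
expiry date is flagged stale but still evaluated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from datetime import date, timedelta
from pathlib import Path

import pandas as pd

from .errors import InputError
from .metrics import FieldMetrics

__all__ = [
    "Baseline",
    "ToleranceSet",
    "ParameterResult",
    "QAResult",
    "create_baseline",
    "save_baseline",
    "load_baseline",
    "evaluate_daily",
]

BASELINE_VALIDITY_DAYS = 365


@dataclass
class Baseline:
    """Benchmark metric set for one machine + beam."""

    metrics: FieldMetrics
    machine_id: str
    created: date
    valid_until: date
    software_state: str = ""

    def __post_init__(self) -> None:
        if self.valid_until <= self.created:
            raise InputError("valid_until must be after created")

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(),
            "machine_id": self.machine_id,
            "created": self.created.isoformat(),
            "valid_until": self.valid_until.isoformat(),
            "software_state": self.software_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Baseline":
        return cls(
            metrics=FieldMetrics.from_dict(d["metrics"]),
            machine_id=d["machine_id"],
            created=date.fromisoformat(d["created"]),
            valid_until=date.fromisoformat(d["valid_until"]),
            software_state=d.get("software_state", ""),
        )


@dataclass(frozen=True)
class ToleranceSet:
    """Per-parameter tolerances; deviations beyond them fail the day."""

    output_pct: float = 2.5
    bq_pct: float = 2.0
    flatness_abs_pct: float = 2.0
    symmetry_abs_pct: float = 2.0
    size_mm: float = 2.0
    center_mm: float = 2.0

    def __post_init__(self) -> None:
        for f in fields(self):
            if not getattr(self, f.name) > 0:
                raise InputError(f"tolerance {f.name} must be > 0")


@dataclass
class ParameterResult:
    """Measured-vs-baseline outcome for one monitored parameter."""

    parameter: str
    measured: float | None
    baseline: float | None
    deviation: float | None  # percent (ratio-type) or same units (difference-type)
    tolerance: float | None
    kind: str  # "ratio_pct" | "diff_pct" | "diff_mm"
    status: str  # "pass" | "fail" | "not_applicable"


@dataclass
class QAResult:
    """Full daily evaluation: one record per parameter plus staleness."""

    machine_id: str
    run_date: date
    parameters: list[ParameterResult] = field(default_factory=list)
    stale_baseline: bool = False

    @property
    def passed(self) -> bool:
        return all(p.status != "fail" for p in self.parameters)

    def to_frame(self) -> pd.DataFrame:
        rows = [(p.parameter, p.measured, p.baseline, p.deviation, p.tolerance,
                 p.kind, p.status) for p in self.parameters]
        df = pd.DataFrame(rows, columns=["parameter", "measured", "baseline",
                                         "deviation", "tolerance", "kind", "status"])
        df["stale_baseline"] = self.stale_baseline
        return df

    def to_dict(self) -> dict:
        return {
            "machine_id": self.machine_id,
            "run_date": self.run_date.isoformat(),
            "stale_baseline": self.stale_baseline,
            "passed": self.passed,
            "parameters": [dict(p.__dict__) for p in self.parameters],
        }


def create_baseline(metrics: FieldMetrics, machine_id: str, created: date,
                    software_state: str = "") -> Baseline:
    """Freeze *metrics* as the benchmark; valid for one year from *created*."""
    if metrics.mu_open is None or not metrics.mu_open > 0:
        raise InputError("baseline requires a positive mu_open")
    if not metrics.fff and (metrics.flatness_x is None or metrics.flatness_y is None):
        raise InputError("baseline for a flattened beam requires flatness values")
    return Baseline(
        metrics=metrics,
        machine_id=machine_id,
        created=created,
        valid_until=created + timedelta(days=BASELINE_VALIDITY_DAYS),
        software_state=software_state,
    )


def save_baseline(baseline: Baseline, path) -> None:
    Path(path).write_text(json.dumps(baseline.to_dict(), indent=2) + "\n")


def load_baseline(path) -> Baseline:
    return Baseline.from_dict(json.loads(Path(path).read_text()))


def _ratio_pct(measured: float, reference: float) -> float:
    return (measured / reference - 1.0) * 100.0


def evaluate_daily(metrics: FieldMetrics, baseline: Baseline, tol: ToleranceSet,
                   run_date: date, machine_id: str | None = None) -> QAResult:
    """Compare today's metric set against the benchmark under *tol*.

    Raises InputError on a machine or beam mismatch.  Comparisons are still
    computed when the baseline has expired; the result is merely flagged
    ``stale_baseline``.
    """
    if machine_id is not None and machine_id != baseline.machine_id:
        raise InputError(f"machine mismatch: {machine_id!r} vs baseline {baseline.machine_id!r}")
    ref = baseline.metrics
    if metrics.beam_label and ref.beam_label and metrics.beam_label != ref.beam_label:
        raise InputError(f"beam mismatch: {metrics.beam_label!r} vs baseline {ref.beam_label!r}")
    if metrics.fff != ref.fff:
        raise InputError("FF/FFF mismatch between daily metrics and baseline")

    result = QAResult(machine_id=baseline.machine_id, run_date=run_date,
                      stale_baseline=run_date > baseline.valid_until)

    def add(parameter: str, measured, reference, tolerance: float, kind: str) -> None:
        if measured is None or reference is None:
            result.parameters.append(ParameterResult(
                parameter, measured, reference, None, tolerance, kind, "not_applicable"))
            return
        dev = _ratio_pct(measured, reference) if kind == "ratio_pct" else measured - reference
        status = "fail" if abs(dev) > tolerance else "pass"
        result.parameters.append(ParameterResult(
            parameter, measured, reference, dev, tolerance, kind, status))

    add("output", metrics.mu_open, ref.mu_open, tol.output_pct, "ratio_pct")
    add("beam_quality", metrics.wedge_factor, ref.wedge_factor, tol.bq_pct, "ratio_pct")
    add("flatness_x", metrics.flatness_x, ref.flatness_x, tol.flatness_abs_pct, "diff_pct")
    add("flatness_y", metrics.flatness_y, ref.flatness_y, tol.flatness_abs_pct, "diff_pct")
    add("symmetry_x", metrics.symmetry_x, ref.symmetry_x, tol.symmetry_abs_pct, "diff_pct")
    add("symmetry_y", metrics.symmetry_y, ref.symmetry_y, tol.symmetry_abs_pct, "diff_pct")
    add("size_x", metrics.size_x, ref.size_x, tol.size_mm, "diff_mm")
    add("size_y", metrics.size_y, ref.size_y, tol.size_mm, "diff_mm")
    add("center_x", metrics.center_x, ref.center_x, tol.center_mm, "diff_mm")
    add("center_y", metrics.center_y, ref.center_y, tol.center_mm, "diff_mm")
    return result
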