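"""Paired native-vs-cam ROM comparison and error statistics.

This is the study-design layer: for each hip the six standard motions
are measured twice (without and with the cam deformity), the per-motion
reduction ``native - cam`` is computed, a motion counts as *limited*
when that reduction strictly exceeds the 5-degree threshold, and the
simulated reductions are scored against a reference measurement
(an electromagnetic-tracker-style ground truth, or the phantom's
analytic oracle) via median / interquartile-range / maximum-absolute
error and a detection confusion table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh_core import ValidationError
from .rom_engine import STANDARD_MOTIONS

__all__ = [
    "ROMRecord",
    "PairedComparison",
    "ErrorStats",
    "DEFAULT_THRESHOLD",
    "compare_conditions",
    "error_vs_reference",
    "error_stats",
    "detection_confusion",
    "read_rom_csv",
    "write_rom_csv",
    "write_report",
]

DEFAULT_THRESHOLD = 5.0  # degrees; "restricted by more than 5 degrees"

MOTION_TITLES = {
    "max_flexion": "Max flexion",
    "max_abduction": "Max abduction",
    "max_ir_0": "Max internal rotation",
    "max_ir_30": "Max internal rotation at 30",
    "max_ir_60": "Max internal rotation at 60",
    "max_ir_90": "Max internal rotation at 90",
}


@dataclass(frozen=True)
class ROMRecord:
    """Six motion endpoints of one hip under one condition."""

    subject: str
    source: str  # "simulation" | "reference"
    condition: str  # "native" | "cam"
    angles: dict  # motion label -> endpoint angle, degrees

    def __post_init__(self):
        if self.source not in ("simulation", "reference"):
            raise ValidationError(f"unknown source {self.source!r}")
        if self.condition not in ("native", "cam"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        missing = [m for m in STANDARD_MOTIONS if m not in self.angles]
        extra = [m for m in self.angles if m not in STANDARD_MOTIONS]
        if missing or extra:
            raise ValidationError(
                f"record must contain exactly the six standard motions "
                f"(missing {missing}, unexpected {extra})"
            )
        bad = {k: v for k, v in self.angles.items() if not np.isfinite(v)}
        if bad:
            raise ValidationError(f"non-finite angles: {bad}")
        object.__setattr__(
            self, "angles", {k: float(v) for k, v in self.angles.items()}
        )


@dataclass(frozen=True)
class PairedComparison:
    """Per-motion native-minus-cam differences with limitation flags."""

    subject: str
    source: str
    native: dict
    cam: dict
    difference: dict  # native - cam, full precision
    limited: dict  # difference > threshold (strict)
    threshold: float


def compare_conditions(
    native: ROMRecord, cam: ROMRecord, threshold: float = DEFAULT_THRESHOLD
) -> PairedComparison:
    """Native-vs-cam reduction per motion, flagged at a strict threshold.

    A motion is *limited* when ``native - cam`` exceeds the threshold
    strictly: a reduction of exactly the threshold is not flagged.
    """
    if native.subject != cam.subject or native.source != cam.source:
        raise ValidationError("paired records must share subject and source")
    if native.condition != "native" or cam.condition != "cam":
        raise ValidationError("expected a native and a cam record, in that order")
    diff = {m: native.angles[m] - cam.angles[m] for m in STANDARD_MOTIONS}
    limited = {m: bool(d > threshold) for m, d in diff.items()}
    return PairedComparison(
        native.subject, native.source, dict(native.angles), dict(cam.angles),
        diff, limited, threshold,
    )


def error_vs_reference(sim: PairedComparison, ref: PairedComparison) -> dict:
    """Per-motion error: simulated reduction minus reference reduction."""
    if set(sim.difference) != set(ref.difference):
        raise ValidationError("motion sets differ between simulation and reference")
    return {m: sim.difference[m] - ref.difference[m] for m in sim.difference}


@dataclass(frozen=True)
class ErrorStats:
    """Descriptive statistics of the simulation-vs-reference errors."""

    median: float
    iqr: tuple  # (25th, 75th percentile), linear interpolation
    max_abs: float
    n: int


def error_stats(errors) -> ErrorStats:
    """Median, interquartile range and maximum absolute error.

    The median of an even-length sample is the mean of the middle two;
    percentiles use linear interpolation between order statistics.
    """
    arr = np.asarray(list(errors), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot compute statistics of an empty error list")
    q25, q75 = np.percentile(arr, [25.0, 75.0])
    return ErrorStats(
        median=float(np.median(arr)),
        iqr=(float(q25), float(q75)),
        max_abs=float(np.abs(arr).max()),
        n=int(arr.size),
    )


def detection_confusion(
    sim: list[PairedComparison],
    ref: list[PairedComparison],
    threshold: float = DEFAULT_THRESHOLD,
) -> dict:
    """Score simulated limitation flags against reference ground truth.

    Flags are re-derived from the stored differences at ``threshold`` so
    both arms use the same cutoff.  Returns TP/FP/FN/TN counts summing to
    n_subjects x n_motions.
    """
    if len(sim) != len(ref):
        raise ValidationError("simulation and reference cohorts differ in size")
    counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    for s, r in zip(sim, ref):
        if s.subject != r.subject:
            raise ValidationError(f"subject mismatch: {s.subject} vs {r.subject}")
        if set(s.difference) != set(r.difference):
            raise ValidationError("motion sets differ between cohorts")
        for m in s.difference:
            sflag = s.difference[m] > threshold
            rflag = r.difference[m] > threshold
            if rflag and sflag:
                counts["tp"] += 1
            elif rflag and not sflag:
                counts["fn"] += 1
            elif sflag:
                counts["fp"] += 1
            else:
                counts["tn"] += 1
    return counts


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["subject", "source", "condition", "motion", "angle_deg"]


def write_rom_csv(records: list[ROMRecord], path) -> None:
    """Long-format ROM table: subject, source, condition, motion, angle."""
    rows = []
    for rec in records:
        for m in STANDARD_MOTIONS:
            rows.append(
                {
                    "subject": rec.subject,
                    "source": rec.source,
                    "condition": rec.condition,
                    "motion": m,
                    "angle_deg": round(rec.angles[m], 1),
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_rom_csv(path) -> list[ROMRecord]:
    """Parse the long-format ROM CSV back into records.

    Malformed rows raise with their line number (header is line 1).
    """
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ValidationError(f"unreadable ROM CSV {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2
        try:
            float(row["angle_deg"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}:{line}: bad angle_deg value {row['angle_deg']!r}"
            ) from None
        if row["motion"] not in STANDARD_MOTIONS:
            raise ValidationError(f"{path}:{line}: unknown motion {row['motion']!r}")
    records = []
    for (subject, source, condition), grp in df.groupby(
        ["subject", "source", "condition"], sort=True
    ):
        angles = {r["motion"]: float(r["angle_deg"]) for _, r in grp.iterrows()}
        records.append(ROMRecord(str(subject), str(source), str(condition), angles))
    return records


def write_report(
    comparisons: list[tuple[PairedComparison, PairedComparison]],
    stats: ErrorStats | None,
    path_csv,
    path_json=None,
) -> None:
    """Per-motion comparison table (CSV) plus a JSON summary.

    Each row mirrors the study's per-hip table: simulated native/cam
    endpoints and their difference, reference native/cam endpoints and
    their difference, and the difference of the differences.  Angles are
    written to 0.1 degree; differences are computed at full precision
    first and rounded last.
    """
    rows = []
    for sim, ref in comparisons:
        for m in STANDARD_MOTIONS:
            rows.append(
                {
                    "subject": sim.subject,
                    "motion": MOTION_TITLES.get(m, m),
                    "sim_native_deg": round(sim.native[m], 1),
                    "sim_cam_deg": round(sim.cam[m], 1),
                    "sim_difference_deg": round(sim.difference[m], 1),
                    "ref_native_deg": round(ref.native[m], 1),
                    "ref_cam_deg": round(ref.cam[m], 1),
                    "ref_difference_deg": round(ref.difference[m], 1),
                    "difference_of_difference_deg": round(
                        sim.difference[m] - ref.difference[m], 1
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    if path_json is not None:
        confusion = detection_confusion(
            [s for s, _ in comparisons], [r for _, r in comparisons]
        )
        summary = {
            "n_hips": len(comparisons),
            "n_endpoints": len(comparisons) * len(STANDARD_MOTIONS),
            "threshold_deg": comparisons[0][0].threshold if comparisons else None,
            "confusion": confusion,
        }
        if stats is not None:
            summary["error_stats"] = {
                "median_deg": stats.median,
                "iqr_deg": list(stats.iqr),
                "max_abs_deg": stats.max_abs,
                "n": stats.n,
            }
        Path(path_json).write_text(json.dumps(summary, indent=2))
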