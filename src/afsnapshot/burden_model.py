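"""Data model and CSV I/O for per-patient daily AT/AF burden series.

A burden series records, for one patient, the number of hours of atrial
tachycardia / atrial fibrillation (AT/AF) on each calendar day since device
implant.  The representation is sparse: days without a row carry zero burden.
Day indexing is 1-based (implant day = day 1).  The first
``DEFAULT_BLANKING_DAYS`` days are conventionally excluded from analysis to
avoid procedure-induced transient AF, and a day counts as an "AF day" only
when its burden strictly exceeds ``DEFAULT_AF_THRESHOLD_MINUTES`` of AT/AF.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

HOURS_PER_DAY = 24.0
DEFAULT_BLANKING_DAYS = 30
DEFAULT_AF_THRESHOLD_MINUTES = 5.0

BURDEN_COLUMNS = ("patient_id", "day_index", "burden_hours")
COVARIATE_COLUMNS = ("patient_id", "chads2", "baseline_flag", "followup_days")


class CohortFormatError(ValueError):
    """Raised when an input file is structurally unreadable (missing columns)."""


class CohortValidationError(ValueError):
    """Raised when rows violate series invariants.

    Attributes
    ----------
    problems : list of str
        One human-readable message per offending line, naming the patient
        and day involved.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "; ".join(self.problems[:5])
        more = "" if len(self.problems) <= 5 else f" (+{len(self.problems) - 5} more)"
        super().__init__(f"{len(self.problems)} invalid row(s): {preview}{more}")


@dataclass(frozen=True)
class DailyBurdenSeries:
    """One patient's sparse per-day AT/AF burden in hours.

    Parameters
    ----------
    patient_id : str
        Opaque identifier.
    burdens : tuple of (int, float)
        ``(day_index, burden_hours)`` pairs with strictly increasing
        1-based day indices; burden in [0, 24].  Days absent from the
        sequence have zero burden.
    followup_days : int
        Last day with device data; day indices must not exceed it.
    """

    patient_id: str
    burdens: tuple[tuple[int, float], ...]
    followup_days: int

    def __post_init__(self):
        object.__setattr__(self, "burdens", tuple((int(d), float(b)) for d, b in self.burdens))
        if self.followup_days < 0:
            raise ValueError(f"patient {self.patient_id}: negative followup_days")
        prev = 0
        for day, b in self.burdens:
            if day <= prev:
                raise ValueError(
                    f"patient {self.patient_id}: day indices must be strictly "
                    f"increasing positive integers (got {day} after {prev})"
                )
            if day > self.followup_days:
                raise ValueError(
                    f"patient {self.patient_id}: day {day} exceeds followup_days "
                    f"{self.followup_days}"
                )
            if not (0.0 <= b <= HOURS_PER_DAY) or math.isnan(b):
                raise ValueError(
                    f"patient {self.patient_id}: burden {b} on day {day} outside [0, 24]"
                )
            prev = day

    def burden_map(self) -> dict[int, float]:
        return dict(self.burdens)

    def days(self) -> np.ndarray:
        return np.array([d for d, _ in self.burdens], dtype=np.int64)

    def hours(self) -> np.ndarray:
        return np.array([b for _, b in self.burdens], dtype=np.float64)

    def burdens_between(self, start_day: int, end_day: int) -> np.ndarray:
        """Hours on the *recorded* days within [start_day, end_day] inclusive.

        Unrecorded days are zero-burden and omitted; callers needing the span
        length must count days themselves.
        """
        return np.array(
            [b for d, b in self.burdens if start_day <= d <= end_day], dtype=np.float64
        )


@dataclass(frozen=True)
class PatientRecord:
    """A burden series plus the covariates used for stratified reporting."""

    series: DailyBurdenSeries
    chads2: int
    on_warfarin_or_aad_at_baseline: bool = False

    def __post_init__(self):
        if not (0 <= int(self.chads2) <= 6):
            raise ValueError(
                f"patient {self.series.patient_id}: chads2 {self.chads2} outside [0, 6]"
            )

    @property
    def patient_id(self) -> str:
        return self.series.patient_id


@dataclass(frozen=True)
class BurdenSummary:
    """Span-level burden metrics for one patient.

    ``avg_burden`` is the mean daily burden over the evaluated span
    (zero-burden days included in the denominator), ``max_daily_burden`` is
    the single worst day, and ``pct_af_days`` the percentage of evaluated
    days whose burden exceeds the AF-day threshold.
    """

    avg_burden: float
    max_daily_burden: float
    pct_af_days: float

    def __post_init__(self):
        if not (0.0 <= self.avg_burden <= self.max_daily_burden <= HOURS_PER_DAY):
            raise ValueError(
                f"require 0 <= avg ({self.avg_burden}) <= max "
                f"({self.max_daily_burden}) <= 24"
            )
        if not (0.0 <= self.pct_af_days <= 100.0):
            raise ValueError(f"pct_af_days {self.pct_af_days} outside [0, 100]")


def is_af_day(burden: float, threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES) -> bool:
    """True iff ``burden`` (hours) strictly exceeds ``threshold_minutes``.

    The strict inequality matches the ">5 minutes on any day" AF-day rule;
    a burden of exactly 5 minutes is not an AF day.
    """
    if not (0.0 <= burden <= HOURS_PER_DAY):
        raise ValueError(f"burden {burden} outside [0, 24]")
    return burden > threshold_minutes / 60.0


def apply_blanking(
    series: DailyBurdenSeries, blanking_days: int = DEFAULT_BLANKING_DAYS
) -> DailyBurdenSeries:
    """Drop the initial post-implant days from a series.

    Returns a series containing only days with ``day_index > blanking_days``
    (so with the default of 30, day 31 is the first retained day);
    ``followup_days`` is unchanged.  Idempotent for a fixed ``blanking_days``.
    """
    if blanking_days < 0:
        raise ValueError("blanking_days must be >= 0")
    kept = tuple((d, b) for d, b in series.burdens if d > blanking_days)
    return replace(series, burdens=kept)


def _resolve_span(series: DailyBurdenSeries, span) -> tuple[int, int]:
    if span is None:
        start, end = 1, series.followup_days
    elif hasattr(span, "start_day") and hasattr(span, "end_day"):
        start, end = int(span.start_day), int(span.end_day)
    else:
        start, end = int(span[0]), int(span[1])
    if start < 1 or end < start:
        raise ValueError(f"empty or invalid span ({start}, {end})")
    if start > series.followup_days:
        raise ValueError(
            f"span starting at day {start} does not overlap follow-up of "
            f"{series.followup_days} days (patient {series.patient_id})"
        )
    return start, min(end, series.followup_days)


def summarize_burden(
    series: DailyBurdenSeries,
    span=None,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
) -> BurdenSummary:
    """Compute avg/max/percent-of-days burden metrics over a span.

    ``span`` may be ``None`` (full follow-up, days 1..followup_days), a
    ``(start_day, end_day)`` pair, or any object exposing ``start_day`` and
    ``end_day`` (e.g. a ``MonitoringWindow``).  The span is truncated at the
    end of follow-up; an empty span raises ``ValueError``.
    """
    start, end = _resolve_span(series, span)
    n_days = end - start + 1
    vals = series.burdens_between(start, end)
    total = float(vals.sum()) if vals.size else 0.0
    mx = float(vals.max()) if vals.size else 0.0
    n_af = int(sum(is_af_day(v, af_threshold_minutes) for v in vals))
    return BurdenSummary(
        avg_burden=total / n_days,
        max_daily_burden=mx,
        pct_af_days=100.0 * n_af / n_days,
    )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Long-form burden file: patient_id, day_index, burden_hours (header required).
# Covariates either in a companion file (patient_id, chads2, baseline_flag,
# followup_days) or embedded as extra columns on every burden row.  Follow-up
# length is carried explicitly because missing late days mean *shorter
# follow-up*, not zero burden.
# ---------------------------------------------------------------------------


def _require_columns(fieldnames, required, path):
    missing = [c for c in required if c not in (fieldnames or [])]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")


def read_cohort(path, covariates_path=None) -> list[PatientRecord]:
    """Read a cohort from long-form CSV, validating every row.

    Rows violating the series invariants (burden outside [0, 24], duplicate
    (patient, day) pairs, non-positive day indices) are collected and
    reported together in a :class:`CohortValidationError`.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, BURDEN_COLUMNS, path)
        embedded = covariates_path is None and all(
            c in reader.fieldnames for c in ("chads2", "baseline_flag", "followup_days")
        )
        if covariates_path is None and not embedded:
            raise CohortFormatError(
                f"{path}: no covariates file given and columns "
                "chads2/baseline_flag/followup_days not embedded"
            )
        problems: list[str] = []
        per_patient: dict[str, dict[int, float]] = {}
        covs: dict[str, tuple[int, bool, int]] = {}
        for lineno, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            try:
                day = int(row["day_index"])
                burden = float(row["burden_hours"])
            except (TypeError, ValueError):
                problems.append(f"line {lineno}: unparseable day/burden for patient {pid}")
                continue
            if day < 1:
                problems.append(f"line {lineno}: patient {pid} day {day} not a positive index")
                continue
            if not (0.0 <= burden <= HOURS_PER_DAY):
                problems.append(
                    f"line {lineno}: patient {pid} day {day} burden {burden} outside [0, 24]"
                )
                continue
            bucket = per_patient.setdefault(pid, {})
            if day in bucket:
                problems.append(f"line {lineno}: duplicate day {day} for patient {pid}")
                continue
            bucket[day] = burden
            if embedded:
                covs[pid] = (int(row["chads2"]), _parse_flag(row["baseline_flag"]),
                             int(row["followup_days"]))
        if covariates_path is not None:
            covs = _read_covariates(covariates_path)
        records = []
        for pid, burden_by_day in per_patient.items():
            if pid not in covs:
                problems.append(f"patient {pid}: no covariate row")
                continue
            chads2, flag, followup = covs[pid]
            try:
                series = DailyBurdenSeries(
                    patient_id=pid,
                    burdens=tuple(sorted(burden_by_day.items())),
                    followup_days=followup,
                )
                records.append(
                    PatientRecord(series=series, chads2=chads2,
                                  on_warfarin_or_aad_at_baseline=flag)
                )
            except ValueError as exc:
                problems.append(str(exc))
        # covariate-only patients (no burden rows => all-zero series)
        for pid, (chads2, flag, followup) in covs.items():
            if pid not in per_patient:
                records.append(
                    PatientRecord(
                        series=DailyBurdenSeries(pid, (), followup),
                        chads2=chads2,
                        on_warfarin_or_aad_at_baseline=flag,
                    )
                )
        if problems:
            raise CohortValidationError(problems)
    records.sort(key=lambda r: r.patient_id)
    return records


def _parse_flag(raw) -> bool:
    return str(raw).strip().lower() in ("1", "true", "t", "yes")


def _read_covariates(path) -> dict[str, tuple[int, bool, int]]:
    path = Path(path)
    covs = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, COVARIATE_COLUMNS, path)
        for row in reader:
            covs[row["patient_id"]] = (
                int(row["chads2"]),
                _parse_flag(row["baseline_flag"]),
                int(row["followup_days"]),
            )
    return covs


def write_cohort(cohort: Iterable[PatientRecord], path, covariates_path) -> None:
    """Write a cohort to the long-form burden CSV plus a covariates CSV.

    Floats are serialised with ``repr`` so that write/read round-trips are
    exact.
    """
    cohort = list(cohort)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(BURDEN_COLUMNS)
        for rec in cohort:
            for day, burden in rec.series.burdens:
                w.writerow([rec.patient_id, day, repr(burden)])
    with open(covariates_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(COVARIATE_COLUMNS)
        for rec in cohort:
            w.writerow(
                [
                    rec.patient_id,
                    rec.chads2,
                    int(rec.on_warfarin_or_aad_at_baseline),
                    rec.series.followup_days,
                ]
            )
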