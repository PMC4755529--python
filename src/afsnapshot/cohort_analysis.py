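"""Cohort-level reporting: eligibility, stratification, detection tables, CIs.

Reproduces the reporting conventions of device-cohort snapshot studies: per
monitoring window, the eligible denominator (patients with device data
covering the whole window), the continuously-monitored ("CIED-detected")
denominator, and the snapshot-detected count, expressed both as a percent of
all eligible patients and as a percent of CIED-detected patients, with 95%
binomial confidence intervals on the rounded count.  Strata: CHADS2 score
(1 vs >=2) and average-burden dichotomies (cohort-median split, default, or
a fixed cutoff such as 5.5 h/day).

CI method note: for printed cells like 126/254 -> 49.6 [43.3-55.9]%, the
Clopper-Pearson (exact beta) interval gives [43.3, 55.9] while Wilson gives
[43.5, 55.7]; Clopper-Pearson matches the published arithmetic and is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import median
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .burden_model import (
    DEFAULT_AF_THRESHOLD_MINUTES,
    DEFAULT_BLANKING_DAYS,
    PatientRecord,
    is_af_day,
    summarize_burden,
)
from .snapshot_simulator import (
    DEFAULT_N_REPS,
    MonitoringWindow,
    simulate_cohort,
)

CiMethod = Literal["clopper_pearson", "wilson"]
_CI_METHOD_MAP = {"clopper_pearson": "beta", "wilson": "wilson"}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, as printed tables do (not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def detection_rate_percent(successes: float, n: int) -> float:
    """Percentage 100 * successes / n, rounded half-up to one decimal."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * successes / n, 1)


def binomial_ci(
    successes: float,
    n: int,
    method: CiMethod = "clopper_pearson",
    level: float = 0.95,
) -> tuple[float, float]:
    """95% binomial CI on the percent scale, one decimal.

    ``successes`` is rounded half-up to an integer first (printed detected
    counts are integers).  ``n == 0`` is undefined and raises.
    """
    if n <= 0:
        raise ValueError("binomial CI undefined for n = 0")
    k = int(round_half_up(successes))
    if not (0 <= k <= n):
        raise ValueError(f"successes {k} outside [0, {n}]")
    if method not in _CI_METHOD_MAP:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=_CI_METHOD_MAP[method])
    return round_half_up(100.0 * lo, 1), round_half_up(100.0 * hi, 1)


# ---------------------------------------------------------------------------
# Eligibility and per-patient window facts
# ---------------------------------------------------------------------------


def eligible_patients(
    cohort: Iterable[PatientRecord], window: MonitoringWindow
) -> list[PatientRecord]:
    """Patients with device data covering the whole window
    (followup_days >= window end day)."""
    return [r for r in cohort if r.series.followup_days >= window.end_day]


def cied_detected_in_window(
    patient: PatientRecord,
    window: MonitoringWindow,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
) -> bool:
    """True iff continuous monitoring sees any AF day (> threshold) in the window."""
    vals = patient.series.burdens_between(window.start_day, window.end_day)
    return any(is_af_day(v, af_threshold_minutes) for v in vals)


# ---------------------------------------------------------------------------
# Strata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumSpec:
    """A named membership rule over patient records; the strata of one
    stratification must partition any cohort."""

    name: str
    predicate: Callable[[PatientRecord], bool]
    cutoff_hours: float | None = None

    def members(self, cohort: Iterable[PatientRecord]) -> list[PatientRecord]:
        return [r for r in cohort if self.predicate(r)]


def whole_cohort_stratum() -> list[StratumSpec]:
    return [StratumSpec(name="all", predicate=lambda r: True)]


def chads2_strata() -> list[StratumSpec]:
    """Intermediate risk (score 1) vs high risk (score >= 2)."""
    return [
        StratumSpec(name="chads2_1", predicate=lambda r: r.chads2 <= 1),
        StratumSpec(name="chads2_ge2", predicate=lambda r: r.chads2 >= 2),
    ]


def _avg_burden(
    record: PatientRecord,
    blanking_days: int,
    af_threshold_minutes: float,
) -> float:
    s = summarize_burden(
        record.series,
        span=(blanking_days + 1, record.series.followup_days),
        af_threshold_minutes=af_threshold_minutes,
    )
    return s.avg_burden


def burden_strata(
    cutoff_hours: float,
    blanking_days: int = DEFAULT_BLANKING_DAYS,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
) -> list[StratumSpec]:
    """Low (< cutoff) vs high (>= cutoff) average daily burden over the
    post-blanking follow-up."""

    def below(r: PatientRecord) -> bool:
        return _avg_burden(r, blanking_days, af_threshold_minutes) < cutoff_hours

    return [
        StratumSpec(name=f"burden_lt_{cutoff_hours:g}", predicate=below,
                    cutoff_hours=cutoff_hours),
        StratumSpec(name=f"burden_ge_{cutoff_hours:g}",
                    predicate=lambda r: not below(r), cutoff_hours=cutoff_hours),
    ]


def median_burden_split(
    cohort: Sequence[PatientRecord],
    blanking_days: int = DEFAULT_BLANKING_DAYS,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
) -> tuple[float, list[StratumSpec]]:
    """Dichotomize at the cohort median average daily burden.

    Low stratum is strictly below the median; high stratum is at or above it
    (ties go high).  Returns the data-derived cutoff and the two strata.
    """
    if not cohort:
        raise ValueError("empty cohort")
    cutoff = float(
        median(_avg_burden(r, blanking_days, af_threshold_minutes) for r in cohort)
    )
    return cutoff, burden_strata(cutoff, blanking_days, af_threshold_minutes)


# ---------------------------------------------------------------------------
# Detection table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowReportRow:
    """One window x stratum row of the detection table.

    Rates are percentages rounded to one decimal; ``None`` marks undefined
    cells (zero denominator).  ``mc_mean_detected`` and
    ``expected_detected`` retain the unrounded machine-readable values.
    """

    stratum: str
    window_length: int
    n_with_data: int
    n_cied_detected: int
    mc_mean_detected: float
    expected_detected: float
    n_snapshot_detected: int
    rate_of_total: float | None
    rate_of_total_ci: tuple[float, float] | None
    rate_of_cied_detected: float | None
    rate_of_cied_detected_ci: tuple[float, float] | None

    def __post_init__(self):
        if not (
            self.n_snapshot_detected <= self.n_cied_detected <= self.n_with_data
        ):
            raise ValueError(
                "require detected <= CIED-detected <= eligible, got "
                f"{self.n_snapshot_detected}/{self.n_cied_detected}/{self.n_with_data}"
            )


def detection_table(
    cohort: Sequence[PatientRecord],
    windows: Sequence[MonitoringWindow],
    strata: Sequence[StratumSpec] | None = None,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    ci_method: CiMethod = "clopper_pearson",
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
    policy: str = "zero",
) -> list[WindowReportRow]:
    """Build the full detection report.

    For each window x stratum: filter to eligible patients, find the
    CIED-detected subset, Monte Carlo the snapshot trials on that subset
    (analytic expectation alongside), round the MC mean count half-up, and
    attach binomial CIs.  Snapshot trials reuse per-patient substreams of
    the master seed, so stratum rows are consistent with the cohort row.
    Empty strata yield rows with n = 0 and undefined rates rather than
    being dropped.
    """
    strata = list(strata) if strata is not None else whole_cohort_stratum()
    rows: list[WindowReportRow] = []
    for window in windows:
        for stratum in strata:
            members = stratum.members(cohort)
            eligible = eligible_patients(members, window)
            detected_by_cied = [
                r for r in eligible
                if cied_detected_in_window(r, window, af_threshold_minutes)
            ]
            sim = simulate_cohort(
                detected_by_cied,
                window,
                n_reps=n_reps,
                af_threshold_minutes=af_threshold_minutes,
                policy=policy,
                seed=seed,
            )
            k = int(round_half_up(sim.mc_mean_detected))
            n_total, n_cied = len(eligible), len(detected_by_cied)
            rows.append(
                WindowReportRow(
                    stratum=stratum.name,
                    window_length=window.length_days,
                    n_with_data=n_total,
                    n_cied_detected=n_cied,
                    mc_mean_detected=sim.mc_mean_detected,
                    expected_detected=sim.expected_detected,
                    n_snapshot_detected=k,
                    rate_of_total=(
                        detection_rate_percent(k, n_total) if n_total else None
                    ),
                    rate_of_total_ci=(
                        binomial_ci(k, n_total, ci_method) if n_total else None
                    ),
                    rate_of_cied_detected=(
                        detection_rate_percent(k, n_cied) if n_cied else None
                    ),
                    rate_of_cied_detected_ci=(
                        binomial_ci(k, n_cied, ci_method) if n_cied else None
                    ),
                )
            )
    return rows


def table_to_dataframe(rows: Sequence[WindowReportRow]) -> pd.DataFrame:
    """Flatten report rows for CSV output."""
    recs = []
    for r in rows:
        recs.append(
            {
                "stratum": r.stratum,
                "window_days": r.window_length,
                "n_with_data": r.n_with_data,
                "n_cied_detected": r.n_cied_detected,
                "n_snapshot_detected": r.n_snapshot_detected,
                "mc_mean_detected": r.mc_mean_detected,
                "expected_detected": r.expected_detected,
                "rate_of_total_pct": r.rate_of_total,
                "rate_of_total_ci_low": r.rate_of_total_ci[0] if r.rate_of_total_ci else None,
                "rate_of_total_ci_high": r.rate_of_total_ci[1] if r.rate_of_total_ci else None,
                "rate_of_cied_pct": r.rate_of_cied_detected,
                "rate_of_cied_ci_low": (
                    r.rate_of_cied_detected_ci[0] if r.rate_of_cied_detected_ci else None
                ),
                "rate_of_cied_ci_high": (
                    r.rate_of_cied_detected_ci[1] if r.rate_of_cied_detected_ci else None
                ),
            }
        )
    return pd.DataFrame.from_records(recs)
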