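"""Once-daily snapshot detection: Bernoulli Monte Carlo and exact expectation.

The model: during a contiguous monitoring window one instantaneous rhythm
snapshot is taken per day.  The snapshot on a day with burden ``b`` hours
succeeds with probability ``b / 24`` (the fraction of the day spent in
AT/AF); detection means at least one successful day in the window.  The
Monte Carlo path repeats the window ``n_reps`` times and averages; the
analytic path evaluates the closed form ``1 - prod(1 - p_d)`` exactly.
Both are exposed so each can serve as an oracle for the other.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .burden_model import (
    DEFAULT_AF_THRESHOLD_MINUTES,
    HOURS_PER_DAY,
    DailyBurdenSeries,
    PatientRecord,
)

DEFAULT_N_REPS = 5000
DEFAULT_START_DAY = 31
STANDARD_WINDOW_LENGTHS = (14, 28, 56, 112, 365)

SubThresholdPolicy = Literal["zero", "raw"]


@dataclass(frozen=True)
class MonitoringWindow:
    """Contiguous span of daily snapshots, spanning
    [start_day, start_day + length_days - 1] inclusive."""

    length_days: int
    start_day: int = DEFAULT_START_DAY

    def __post_init__(self):
        if self.start_day < 1:
            raise ValueError("start_day must be >= 1")
        if self.length_days < 1:
            raise ValueError("length_days must be >= 1")

    @property
    def end_day(self) -> int:
        return self.start_day + self.length_days - 1


@dataclass(frozen=True)
class DetectionOutcome:
    """Per-patient, per-window detection result."""

    patient_id: str
    window: MonitoringWindow
    analytic_prob: float
    mc_detect_fraction: float
    n_reps: int

    def __post_init__(self):
        if not (0.0 <= self.analytic_prob <= 1.0):
            raise ValueError("analytic_prob outside [0, 1]")
        if not (0.0 <= self.mc_detect_fraction <= 1.0):
            raise ValueError("mc_detect_fraction outside [0, 1]")


def daily_probability(
    burden: float,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
    policy: SubThresholdPolicy = "zero",
) -> float:
    """Snapshot success probability for one day of burden ``burden`` hours.

    6 hours of AT/AF is a 6/24 = 25% chance that the daily snapshot lands
    inside an episode.  Under the default ``zero`` policy, days at or below
    the AF-day threshold (5 minutes) contribute nothing — such days do not
    meet the AT/AF definition; under ``raw`` the ratio is used unchanged.
    """
    if not (0.0 <= burden <= HOURS_PER_DAY):
        raise ValueError(f"burden {burden} outside [0, 24]")
    if policy not in ("zero", "raw"):
        raise ValueError(f"unknown policy {policy!r}")
    if policy == "zero" and burden <= af_threshold_minutes / 60.0:
        return 0.0
    return burden / HOURS_PER_DAY


def window_probabilities(
    series: DailyBurdenSeries,
    window: MonitoringWindow,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
    policy: SubThresholdPolicy = "zero",
) -> np.ndarray:
    """Per-day success probabilities for the recorded days in the window.

    Days without a data row are zero-probability trials and are omitted
    (they cannot affect either estimator).
    """
    vals = series.burdens_between(window.start_day, window.end_day)
    probs = np.array([daily_probability(b, af_threshold_minutes, policy) for b in vals])
    return probs[probs > 0.0]


def analytic_window_prob(
    series: DailyBurdenSeries,
    window: MonitoringWindow,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
    policy: SubThresholdPolicy = "zero",
) -> float:
    """Exact probability of >=1 successful snapshot: 1 - prod(1 - p_d)."""
    probs = window_probabilities(series, window, af_threshold_minutes, policy)
    if probs.size == 0:
        return 0.0
    if np.any(probs >= 1.0):
        return 1.0
    return float(-np.expm1(np.log1p(-probs).sum()))


def patient_rng(master_seed: int, patient_id: str) -> np.random.Generator:
    """Deterministic per-patient generator derived from a master seed.

    The substream key is a stable hash of the patient id, so subsetting a
    cohort (e.g. to a stratum) never shifts other patients' draws.
    """
    digest = hashlib.sha256(str(patient_id).encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(master_seed), key)))


def simulate_patient_window(
    series: DailyBurdenSeries,
    window: MonitoringWindow,
    n_reps: int = DEFAULT_N_REPS,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
    policy: SubThresholdPolicy = "zero",
    rng: np.random.Generator | None = None,
) -> DetectionOutcome:
    """Monte Carlo the daily Bernoulli trials over one window.

    Each repetition draws one Bernoulli trial per window day; the detection
    fraction is the share of repetitions with at least one success.  The
    analytic probability for the same inputs is filled in alongside.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    probs = window_probabilities(series, window, af_threshold_minutes, policy)
    if probs.size == 0:
        frac = 0.0
        analytic = 0.0
    else:
        draws = rng.random((n_reps, probs.size))
        frac = float(np.any(draws < probs, axis=1).mean())
        if np.any(probs >= 1.0):
            analytic = 1.0
        else:
            analytic = float(-np.expm1(np.log1p(-probs).sum()))
    return DetectionOutcome(
        patient_id=series.patient_id,
        window=window,
        analytic_prob=analytic,
        mc_detect_fraction=frac,
        n_reps=n_reps,
    )


@dataclass(frozen=True)
class CohortSimulation:
    """Cohort-level simulation output: per-patient outcomes plus totals."""

    outcomes: tuple[DetectionOutcome, ...]
    expected_detected: float  # sum of analytic probabilities
    mc_mean_detected: float  # sum of MC detection fractions

    def __len__(self) -> int:
        return len(self.outcomes)


def simulate_cohort(
    cohort: Iterable[PatientRecord | DailyBurdenSeries],
    window: MonitoringWindow,
    n_reps: int = DEFAULT_N_REPS,
    af_threshold_minutes: float = DEFAULT_AF_THRESHOLD_MINUTES,
    policy: SubThresholdPolicy = "zero",
    seed: int = 0,
) -> CohortSimulation:
    """Run the per-patient simulation across a (pre-filtered) cohort.

    The caller is responsible for eligibility filtering.  A single master
    seed deterministically derives one substream per patient via
    :func:`patient_rng`.  ``expected_detected`` is the exact expectation of
    the detected count (sum of analytic probabilities; the count itself is
    Poisson-binomial); ``mc_mean_detected`` is its Monte Carlo counterpart.
    """
    outcomes = []
    for item in cohort:
        series = item.series if isinstance(item, PatientRecord) else item
        rng = patient_rng(seed, series.patient_id)
        outcomes.append(
            simulate_patient_window(
                series, window, n_reps, af_threshold_minutes, policy, rng
            )
        )
    expected = float(sum(o.analytic_prob for o in outcomes))
    mc_mean = float(sum(o.mc_detect_fraction for o in outcomes))
    return CohortSimulation(
        outcomes=tuple(outcomes),
        expected_detected=expected,
        mc_mean_detected=mc_mean,
    )
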