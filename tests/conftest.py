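import numpy as np
import pytest
from hypothesis import strategies as st

from afsnapshot import (
    DailyBurdenSeries,
    LogNormalSpec,
    PatientRecord,
    SyntheticCohortParams,
    generate_cohort,
)


def make_series(patient_id="P1", burdens=(), followup=400):
    return DailyBurdenSeries(
        patient_id=patient_id, burdens=tuple(burdens), followup_days=followup
    )


def constant_series(burden, n_days=400, patient_id="P1", start=1):
    return make_series(
        patient_id,
        tuple((d, burden) for d in range(start, start + n_days)),
        followup=start + n_days - 1,
    )


@st.composite
def burden_series_strategy(draw, max_followup=150, max_days=40):
    followup = draw(st.integers(min_value=1, max_value=max_followup))
    days = draw(
        st.lists(
            st.integers(min_value=1, max_value=followup),
            unique=True,
            max_size=min(followup, max_days),
        )
    )
    hours = st.floats(min_value=0.0, max_value=24.0, allow_nan=False)
    burdens = tuple(sorted((d, draw(hours)) for d in days))
    return make_series("H1", burdens, followup)


@st.composite
def patient_record_strategy(draw, **kw):
    series = draw(burden_series_strategy(**kw))
    chads2 = draw(st.integers(min_value=0, max_value=6))
    flag = draw(st.booleans())
    return PatientRecord(series=series, chads2=chads2, on_warfarin_or_aad_at_baseline=flag)


def random_cohort(rng, n=30, max_followup=150):
    """Plain-numpy random cohort (independent of the synthetic generator)."""
    records = []
    for i in range(n):
        followup = int(rng.integers(31, max_followup + 1))
        n_days = int(rng.integers(0, min(followup, 25) + 1))
        days = sorted(rng.choice(np.arange(1, followup + 1), size=n_days, replace=False).tolist())
        burdens = tuple((int(d), float(rng.uniform(0, 24))) for d in days)
        records.append(
            PatientRecord(
                series=DailyBurdenSeries(f"R{i:03d}", burdens, followup),
                chads2=int(rng.integers(0, 7)),
                on_warfarin_or_aad_at_baseline=bool(rng.integers(0, 2)),
            )
        )
    return records


@pytest.fixture(scope="session")
def default_cohort_370():
    """The calibrated default synthetic cohort at a fixed seed."""
    return generate_cohort(SyntheticCohortParams(seed=20160211))


@pytest.fixture(scope="session")
def small_cohort():
    params = SyntheticCohortParams(
        n_patients=40,
        seed=11,
        followup_days_range=(100, 200),
        af_day_rate_dist=LogNormalSpec(0.05, 1.0),
        burden_dist=LogNormalSpec(2.0, 1.0),
        persistent_fraction=0.1,
    )
    return generate_cohort(params)
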