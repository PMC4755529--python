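import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afsnapshot import (
    DailyBurdenSeries,
    MonitoringWindow,
    analytic_window_prob,
    daily_probability,
    simulate_cohort,
    simulate_patient_window,
)
from afsnapshot.snapshot_simulator import patient_rng, window_probabilities

from conftest import burden_series_strategy, constant_series, make_series


def brute_force_window_prob(probs):
    """Enumerate every Bernoulli outcome combination; independent oracle."""
    total = 0.0
    for outcome in product([0, 1], repeat=len(probs)):
        if not any(outcome):
            continue
        w = 1.0
        for p, hit in zip(probs, outcome):
            w *= p if hit else (1.0 - p)
        total += w
    return total


class TestDailyProbability:
    def test_six_hours_is_25_percent(self):
        assert daily_probability(6.0) == pytest.approx(0.25)

    def test_full_day_certain(self):
        assert daily_probability(24.0) == 1.0

    def test_sub_threshold_policies(self):
        # 3 minutes of AF: below the 5-minute AF-day threshold
        assert daily_probability(0.05, policy="zero") == 0.0
        assert daily_probability(0.05, policy="raw") == pytest.approx(0.05 / 24.0)

    def test_exact_threshold_zeroed(self):
        assert daily_probability(5.0 / 60.0, policy="zero") == 0.0

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            daily_probability(-1.0)
        with pytest.raises(ValueError):
            daily_probability(24.5)

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            daily_probability(1.0, policy="bogus")


class TestAnalyticWindowProb:
    def test_constant_six_hours_fourteen_days(self):
        s = constant_series(6.0, n_days=14, start=31)
        w = MonitoringWindow(length_days=14)
        assert analytic_window_prob(s, w) == pytest.approx(1.0 - 0.75**14)

    def test_zero_burden(self):
        s = make_series(burdens=[], followup=400)
        assert analytic_window_prob(s, MonitoringWindow(length_days=365)) == 0.0

    def test_full_day_absorbing(self):
        s = make_series(burdens=[(100, 24.0)], followup=400)
        assert analytic_window_prob(s, MonitoringWindow(length_days=365)) == 1.0

    def test_days_outside_window_ignored(self):
        s = make_series(burdens=[(10, 12.0), (31, 6.0)], followup=400)
        w = MonitoringWindow(length_days=14)
        assert analytic_window_prob(s, w) == pytest.approx(0.25)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=24.0, allow_nan=False),
                 min_size=1, max_size=3)
    )
    def test_brute_force_oracle_tiny_windows(self, hours):
        s = make_series(
            burdens=[(31 + i, h) for i, h in enumerate(hours)], followup=100
        )
        w = MonitoringWindow(length_days=3)
        probs = [daily_probability(h) for h in hours]
        assert analytic_window_prob(s, w) == pytest.approx(
            brute_force_window_prob(probs), abs=1e-12
        )

    @given(burden_series_strategy(max_followup=120), st.integers(1, 60), st.integers(1, 60))
    @settings(max_examples=100)
    def test_monotone_in_window_length(self, series, len_a, len_b):
        short, long = sorted((len_a, len_b))
        w_short = MonitoringWindow(length_days=short, start_day=1)
        w_long = MonitoringWindow(length_days=long, start_day=1)
        assert analytic_window_prob(series, w_short) <= analytic_window_prob(series, w_long) + 1e-12

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        hours = rng.uniform(0, 24, size=10)
        w = MonitoringWindow(length_days=10, start_day=1)
        base = analytic_window_prob(
            make_series(burdens=list(enumerate(hours, start=1)), followup=10), w
        )
        for _ in range(5):
            rng.shuffle(hours)
            s = make_series(burdens=list(enumerate(hours, start=1)), followup=10)
            assert analytic_window_prob(s, w) == pytest.approx(base, rel=1e-12)

    @given(burden_series_strategy(max_followup=60))
    @settings(max_examples=100)
    def test_policy_dominance(self, series):
        w = MonitoringWindow(length_days=60, start_day=1)
        assert analytic_window_prob(series, w, policy="raw") >= analytic_window_prob(
            series, w, policy="zero"
        ) - 1e-12


class TestMonitoringWindow:
    def test_span(self):
        w = MonitoringWindow(length_days=14)
        assert (w.start_day, w.end_day) == (31, 44)

    @pytest.mark.parametrize("kw", [dict(length_days=0), dict(length_days=5, start_day=0)])
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            MonitoringWindow(**kw)


class TestSimulatePatientWindow:
    def test_zero_burden_never_detects(self):
        s = make_series(burdens=[], followup=100)
        out = simulate_patient_window(
            s, MonitoringWindow(length_days=14), n_reps=200,
            rng=np.random.default_rng(0),
        )
        assert out.mc_detect_fraction == 0.0 and out.analytic_prob == 0.0

    def test_certain_day_always_detects(self):
        s = make_series(burdens=[(35, 24.0)], followup=100)
        out = simulate_patient_window(
            s, MonitoringWindow(length_days=14), n_reps=200,
            rng=np.random.default_rng(0),
        )
        assert out.mc_detect_fraction == 1.0 and out.analytic_prob == 1.0

    def test_mc_within_four_se_of_closed_form(self):
        s = constant_series(6.0, n_days=14, start=31)
        out = simulate_patient_window(
            s, MonitoringWindow(length_days=14), n_reps=5000,
            rng=np.random.default_rng(42),
        )
        p = 1.0 - 0.75**14
        se = math.sqrt(p * (1 - p) / 5000)
        assert abs(out.mc_detect_fraction - p) <= 4 * se

    def test_deterministic_given_rng_seed(self):
        s = constant_series(3.0, n_days=30, start=31)
        w = MonitoringWindow(length_days=30)
        a = simulate_patient_window(s, w, 1000, rng=np.random.default_rng(7))
        b = simulate_patient_window(s, w, 1000, rng=np.random.default_rng(7))
        assert a == b

    def test_n_reps_validated(self):
        with pytest.raises(ValueError):
            simulate_patient_window(make_series(), MonitoringWindow(length_days=1), n_reps=0)


class TestSimulateCohort:
    @staticmethod
    def _half_prob_patient(pid):
        # burden 12 h on the single window day -> p = 0.5
        return make_series(patient_id=pid, burdens=[(31, 12.0)], followup=100)

    def test_linearity_of_expectation(self):
        cohort = [self._half_prob_patient("A"), self._half_prob_patient("B")]
        sim = simulate_cohort(cohort, MonitoringWindow(length_days=1), n_reps=100, seed=0)
        assert sim.expected_detected == pytest.approx(1.0)

    def test_empty_cohort(self):
        sim = simulate_cohort([], MonitoringWindow(length_days=14), seed=0)
        assert len(sim) == 0 and sim.expected_detected == 0.0

    def test_same_seed_identical(self, small_cohort):
        w = MonitoringWindow(length_days=28)
        a = simulate_cohort(small_cohort, w, n_reps=500, seed=9)
        b = simulate_cohort(small_cohort, w, n_reps=500, seed=9)
        assert a == b

    def test_subset_preserves_substreams(self, small_cohort):
        w = MonitoringWindow(length_days=28)
        full = simulate_cohort(small_cohort, w, n_reps=500, seed=9)
        sub = simulate_cohort(small_cohort[:5], w, n_reps=500, seed=9)
        assert sub.outcomes == full.outcomes[:5]

    def test_mc_mean_within_poisson_binomial_bound(self, small_cohort):
        w = MonitoringWindow(length_days=56)
        n_reps = 2000
        sim = simulate_cohort(small_cohort, w, n_reps=n_reps, seed=4)
        var = sum(o.analytic_prob * (1 - o.analytic_prob) for o in sim.outcomes) / n_reps
        assert abs(sim.mc_mean_detected - sim.expected_detected) <= 4 * math.sqrt(var) + 1e-9


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_mc_converges_to_analytic(self, seed):
        rng = np.random.default_rng(seed)
        followup = 120
        n_days = int(rng.integers(1, 20))
        days = np.sort(rng.choice(np.arange(31, followup + 1), n_days, replace=False))
        s = make_series(
            burdens=[(int(d), float(rng.uniform(0, 24))) for d in days], followup=followup
        )
        length = int(rng.integers(1, 90))
        w = MonitoringWindow(length_days=length)
        out = simulate_patient_window(s, w, n_reps=5000, rng=np.random.default_rng(seed + 1000))
        p = out.analytic_prob
        se = math.sqrt(p * (1 - p) / 5000)
        assert abs(out.mc_detect_fraction - p) <= 4 * se + 1e-12


def test_patient_rng_stable_across_runs():
    a = patient_rng(3, "X1").random(4)
    b = patient_rng(3, "X1").random(4)
    c = patient_rng(3, "X2").random(4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_window_probabilities_drop_zero_days():
    s = make_series(burdens=[(31, 0.0), (32, 6.0), (33, 0.04)], followup=100)
    probs = window_probabilities(s, MonitoringWindow(length_days=14))
    np.testing.assert_allclose(probs, [0.25])
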