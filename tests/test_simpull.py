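import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimerlens.errors import AnalysisError
from dimerlens.simpull import (
    DISCARDED,
    TwoColorCounts,
    aggregate_conditions,
    count_steps,
    dimerization_by_condition,
    estimate_dimer_fraction,
    percent_dimerization,
    step_distribution,
    two_color_ratio,
)
from dimerlens.synthetic import simulate_bleach_traces, simulate_photobleaching


def _spots(steps, movie="m0"):
    return pd.DataFrame({
        "movie_id": movie, "spot_id": [f"s{i}" for i in range(len(steps))],
        "steps": steps, "condition": "c", "channel": "LD555",
    })


class TestStepDistribution:
    def test_half_two_step(self):
        out = step_distribution(_spots([1, 1, 2, 2]))
        assert out.loc[0, "percent_two_step"] == 50.0

    def test_all_two_step(self):
        out = step_distribution(_spots([2, 2, 2, 2]))
        assert out.loc[0, "percent_two_step"] == 100.0
        assert out.loc[0, "fraction_1"] == 0.0

    def test_discarded_excluded_from_denominator(self):
        out = step_distribution(_spots([2, 2, DISCARDED, DISCARDED]))
        assert out.loc[0, "n_analyzed"] == 2
        assert out.loc[0, "percent_two_step"] == 100.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        out = step_distribution(_spots(list(rng.integers(1, 5, 200))))
        total = sum(out.loc[0, f"fraction_{s}"] for s in range(1, 5))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_published_proportions_roundtrip(self):
        """1598 spots at 54.1 / 41.4 / 4.5 percent (1 / 2 / >=3 steps)."""
        n = 1598
        n1, n2 = round(n * 0.541), round(n * 0.414)
        n3 = n - n1 - n2
        steps = [1] * n1 + [2] * n2 + [3] * n3
        out = step_distribution(_spots(steps))
        assert out.loc[0, "percent_two_step"] == pytest.approx(41.4, abs=0.05)
        assert out.loc[0, "fraction_1"] * 100 == pytest.approx(54.1, abs=0.05)


class TestPercentDimerization:
    @pytest.mark.parametrize("observed,expected", [
        (55.0, 100.0),   # calibration maximum
        (5.0, 0.0),      # calibration minimum (background)
        (41.4, 72.8),    # direct arithmetic
    ])
    def test_calibration_formula(self, observed, expected):
        assert percent_dimerization(observed) == pytest.approx(expected, abs=1e-12)

    def test_affine_strictly_increasing(self):
        xs = np.linspace(0, 70, 15)
        ys = [percent_dimerization(x) for x in xs]
        assert np.all(np.diff(ys) > 0)
        # affine: second differences vanish
        assert np.allclose(np.diff(ys, 2), 0.0, atol=1e-9)

    def test_values_not_clipped(self):
        assert percent_dimerization(60.0) > 100.0
        assert percent_dimerization(2.0) < 0.0

    def test_invalid_calibration(self):
        with pytest.raises(AnalysisError, match="calibration"):
            percent_dimerization(30.0, min_value=55.0, max_value=5.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        lo=st.floats(0.0, 40.0),
        span=st.floats(1.0, 80.0),
        x=st.floats(-10.0, 110.0),
        dx=st.floats(0.1, 20.0),
    )
    def test_endpoints_and_monotonicity_any_calibration(self, lo, span, x, dx):
        hi = lo + span
        assert percent_dimerization(lo, lo, hi) == pytest.approx(0.0, abs=1e-9)
        assert percent_dimerization(hi, lo, hi) == pytest.approx(100.0, abs=1e-9)
        assert percent_dimerization(x + dx, lo, hi) > percent_dimerization(x, lo, hi)


class TestAggregateConditions:
    def test_identical_distributions_no_change(self):
        out = aggregate_conditions(
            {"none": [50.0, 50.0], "drug": [50.0, 50.0]}, "none")
        drug = out[out.condition == "drug"].iloc[0]
        assert drug["percent_change_vs_reference"] == 0.0

    def test_hand_computed_shift(self):
        out = aggregate_conditions(
            {"none": [50.0, 50.0], "drug": [70.0, 80.0]}, "none")
        drug = out[out.condition == "drug"].iloc[0]
        assert drug["percent_change_vs_reference"] == pytest.approx(50.0)
        assert drug["sem"] == pytest.approx(np.std([70, 80], ddof=1) / np.sqrt(2))

    def test_single_movie_sem_undefined(self):
        out = aggregate_conditions({"none": [50.0], "drug": [60.0]}, "none")
        assert np.isnan(out[out.condition == "drug"].iloc[0]["sem"])

    def test_missing_reference(self):
        with pytest.raises(AnalysisError, match="reference condition absent"):
            aggregate_conditions({"drug": [1.0]}, "none")


class TestTwoColorRatio:
    def test_background_equal_green_zero(self):
        out = two_color_ratio(TwoColorCounts(100, 50, 50), 0.5)
        assert out["normalized_ratio"] == 0.0

    def test_hand_arithmetic(self):
        out = two_color_ratio(TwoColorCounts(500, 300, 50), 0.5)
        assert out["raw_ratio"] == pytest.approx(0.5)
        assert out["normalized_ratio"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = two_color_ratio(TwoColorCounts(500, 300, 50), 0.5)
        b = two_color_ratio(TwoColorCounts(5000, 3000, 500), 0.5)
        assert a["normalized_ratio"] == pytest.approx(b["normalized_ratio"])

    def test_no_bait_spots(self):
        with pytest.raises(AnalysisError, match="no bait"):
            two_color_ratio(TwoColorCounts(0, 10, 1), 0.5)


class TestCountSteps:
    def test_noiseless_two_step(self):
        trace = np.array([200.0] * 40 + [100.0] * 40 + [0.0] * 40)
        assert count_steps(trace, noise_sd=1.0) == 2

    def test_noiseless_one_step(self):
        trace = np.array([150.0] * 50 + [0.0] * 50)
        assert count_steps(trace, noise_sd=1.0) == 1

    def test_nonpositive_trace_discarded(self):
        assert count_steps(np.zeros(50)) == DISCARDED

    def test_accuracy_on_synthetic_traces(self):
        """>= 95% correct at step amplitude >= 8x noise sd."""
        counts_true = ([1] * 125 + [2] * 125 + [3] * 125 + [4] * 125)
        traces, truth = simulate_bleach_traces(
            counts_true, amplitude=80.0, noise_sd=10.0, seed=9)
        correct = sum(count_steps(tr, noise_sd=10.0) == k
                      for tr, k in zip(traces, truth))
        assert correct / len(truth) >= 0.95


class TestRecoveryLoop:
    def test_dimer_fraction_recovery(self):
        table, _ = simulate_photobleaching(
            2000, dimer_fraction=0.8, label_efficiency=0.71, seed=5)
        low = table[table.steps.astype(int) <= 2]
        t = float((low.steps == 2).mean())
        f_hat = estimate_dimer_fraction(t, 0.71)
        assert abs(f_hat - 0.8) <= 0.05

    def test_obligate_dimer_calibration_constant(self):
        """f_d = 1 at p = 0.7097 lands near the 55% two-step anchor."""
        table, man = simulate_photobleaching(
            5000, dimer_fraction=1.0, label_efficiency=0.7097,
            coincidence_rate=0.0, seed=6)
        pct = float((table.steps == 2).mean() * 100)
        assert abs(pct - 55.0) <= 2.0
        assert man["expected_two_step_fraction"] == pytest.approx(
            0.7097 / (2 - 0.7097), abs=1e-12)

    def test_per_condition_pipeline(self):
        table, _ = simulate_photobleaching(
            1200, dimer_fraction=1.0, label_efficiency=0.7097,
            coincidence_rate=0.0, seed=8, condition="TMD")
        res = dimerization_by_condition(table)["TMD"]
        assert res.n_movies == 4
        assert 80 <= res.mean_percent_dimerization <= 120
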