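"""Force-error metrics, quartile labels, and trend statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwdecode import behavior
from mwdecode.behavior import (
    SizeError,
    force_error,
    paired_condition_test,
    quartile_label,
    sliding_force_error,
    trend_slope_test,
    trial_error,
)


class TestForceError:
    def test_perfect_tracking_is_zero(self):
        t = np.linspace(1, 2, 50)
        assert force_error(t, t) == 0.0

    def test_zero_output_is_one(self):
        t = np.linspace(1, 2, 50)
        assert force_error(t, np.zeros_like(t)) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # (1 + 1) / (4 + 4)
        assert force_error([2, 2], [1, 3]) == pytest.approx(0.25)

    def test_all_zero_target_rejected(self):
        with pytest.raises(ZeroDivisionError):
            force_error([0, 0], [1, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(SizeError):
            force_error([1, 2], [1, 2, 3])

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        t = rng.uniform(0.5, 3.0, 40)
        o = t + rng.normal(0, 0.2, 40)
        assert force_error(c * t, c * o) == pytest.approx(force_error(t, o))


class TestSlidingForceError:
    def test_window_count_for_default_scheme(self):
        t = np.full(3000, 2.0)
        fes = sliding_force_error(t, t)
        assert fes.values.size == 21
        assert fes.step == 100

    def test_perfect_tracking_all_zero(self):
        t = np.linspace(1, 3, 3000)
        assert np.all(sliding_force_error(t, t).values == 0.0)

    def test_constant_offset_on_constant_target_is_constant(self):
        t = np.full(3000, 2.0)
        fes = sliding_force_error(t, t + 0.5)
        assert np.ptp(fes.values) == pytest.approx(0.0)

    def test_invalid_overlap_rejected(self):
        t = np.full(3000, 2.0)
        with pytest.raises(ValueError):
            sliding_force_error(t, t, overlap=1.0)


class TestTrialError:
    def test_sum_of_windows(self):
        fes = behavior.ForceErrorSeries(np.array([0.1, 0.2, 0.3]),
                                        np.array([0, 1, 2]), 10, 1)
        assert trial_error(fes) == pytest.approx(0.6)

    def test_empty_rejected(self):
        fes = behavior.ForceErrorSeries(np.array([]), np.array([]), 10, 1)
        with pytest.raises(SizeError):
            trial_error(fes)


class TestQuartileLabel:
    @pytest.mark.parametrize("n,expected", [(36, 9), (48, 12)])
    def test_per_condition_counts(self, n, expected, rng):
        labels = quartile_label(rng.permutation(n).astype(float))
        labs = list(labels.labels)
        assert labs.count("onT") == labs.count("MW") == expected
        assert labels.n_per_condition == expected

    def test_all_equal_ratings_still_balanced(self):
        labels = quartile_label(np.full(36, 50.0))
        labs = np.asarray(labels.labels)
        # deterministic tie-break by trial order
        assert np.all(labs[:9] == "onT")
        assert np.all(labs[-9:] == "MW")

    def test_non_multiple_of_four(self, rng):
        labels = quartile_label(rng.uniform(0, 100, 10))
        labs = list(labels.labels)
        assert labs.count("onT") == labs.count("MW") == 2

    def test_too_few_trials_rejected(self):
        with pytest.raises(SizeError):
            quartile_label(np.arange(7.0))


class TestTrendSlopeTest:
    def test_strictly_increasing_series_significant(self):
        data = [np.arange(12.0) * (i + 1) for i in range(9)]
        _, t, p = trend_slope_test(data)
        assert p < 0.05

    def test_constant_series_give_null(self):
        data = [np.full(10, 5.0) for _ in range(5)]
        slopes, t, p = trend_slope_test(data)
        assert np.all(slopes == 0.0)
        assert t == 0.0 and p == pytest.approx(0.5)

    def test_sign_flip_symmetry(self, rng):
        data = [rng.normal(size=15) + 0.1 * np.arange(15) for _ in range(8)]
        _, _, p_pos = trend_slope_test(data)
        _, _, p_neg = trend_slope_test([-d for d in data])
        assert p_pos + p_neg == pytest.approx(1.0)


class TestPairedConditionTest:
    def test_identical_conditions(self):
        t, p = paired_condition_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_constant_difference_flagged_infinite(self):
        t, p = paired_condition_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert np.isinf(t) and t < 0 and p == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=9), rng.normal(size=9)
        t_ab, p_ab = paired_condition_test(a, b)
        t_ba, p_ba = paired_condition_test(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_single_pair_rejected(self):
        with pytest.raises(SizeError):
            paired_condition_test([1.0], [2.0])
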