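"""Synthetic-data generator: determinism, calibration, injected effects."""

import numpy as np
import pytest

from mwdecode import (
    EffectConfig,
    TaskConfig,
    gen_dataset,
    gen_eeg_epoch,
    gen_output_force,
    gen_ratings,
    gen_target_force,
)
from mwdecode import behavior, connectivity, spectral
from mwdecode.config import ConfigurationError


class TestTargetForce:
    def test_spans_allowable_range_exactly(self):
        f = gen_target_force()
        assert f.min() == pytest.approx(0.5)
        assert f.max() == pytest.approx(3.17)

    def test_deterministic(self):
        assert np.array_equal(gen_target_force(), gen_target_force())

    def test_nonlinear_in_time(self):
        # Affine fit by the normal equations must leave residual.
        f = gen_target_force()
        t = np.arange(f.size, dtype=float)
        X = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(X.T @ X, X.T @ f)
        residual = float(np.sum((f - X @ beta) ** 2))
        assert residual > 1.0


class TestRatings:
    def test_mean_fitted_slope_matches_configured_drift(self):
        eff = EffectConfig()
        slopes = []
        for rep in range(300):
            r = gen_ratings(36, eff, rng_seed=rep)
            slopes.append(np.polyfit(np.arange(36), r, 1)[0])
        assert np.mean(slopes) == pytest.approx(eff.rating_slope, rel=0.05)

    def test_zero_slope_zero_noise_is_constant(self):
        eff = EffectConfig(rating_slope=0.0, rating_noise_sd=0.0)
        r = gen_ratings(12, eff, rng_seed=0)
        assert np.ptp(r) == 0.0

    def test_deterministic_and_bounded(self):
        a = gen_ratings(36, rng_seed=5)
        b = gen_ratings(36, rng_seed=5)
        assert np.array_equal(a, b)
        assert a.min() >= 0.0 and a.max() <= 100.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            gen_ratings(7)


class TestOutputForce:
    def test_zero_noise_gives_zero_error(self):
        target = gen_target_force()
        out = gen_output_force(target, "onT",
                               EffectConfig(force_noise_sd=0.0), rng_seed=0)
        fes = behavior.sliding_force_error(target, out)
        assert behavior.trial_error(fes) == 0.0

    def test_mw_errors_exceed_ont_errors(self):
        target = gen_target_force()
        be = {}
        for cond in ("onT", "MW"):
            vals = [
                behavior.trial_error(behavior.sliding_force_error(
                    target, gen_output_force(target, cond, rng_seed=i)))
                for i in range(100)
            ]
            be[cond] = np.mean(vals)
        assert be["MW"] > be["onT"]

    def test_deterministic_and_clipped(self):
        target = gen_target_force()
        a = gen_output_force(target, "MW", rng_seed=3)
        b = gen_output_force(target, "MW", rng_seed=3)
        assert np.array_equal(a, b)
        cfg = TaskConfig()
        assert a.min() >= cfg.force_min and a.max() <= cfg.force_max


class TestEegEpoch:
    def test_shape_and_determinism(self, montage):
        a = gen_eeg_epoch("MW", montage, rng_seed=1)
        b = gen_eeg_epoch("MW", montage, rng_seed=1)
        assert a.shape == (64, 3000)
        assert np.array_equal(a, b)

    def test_neutral_effects_make_conditions_exchangeable(self, montage):
        # With a neutral effect config the condition level enters every
        # mixing weight with coefficient zero, so the generated epochs are
        # bit-identical across conditions at the same seed.
        eff = EffectConfig.neutral()
        a = gen_eeg_epoch("onT", montage, eff, rng_seed=7)
        b = gen_eeg_epoch("MW", montage, eff, rng_seed=7)
        assert np.array_equal(a, b)

    def test_full_coupling_zero_noise_locks_phases(self, montage):
        eff = EffectConfig(plv_coupling_mw=1.0, pink_rms=0.0,
                           alpha_amp=0.0, theta_amp=0.0,
                           mi_gain_ont=0.0, mi_gain_mw=0.0)
        ep = gen_eeg_epoch("MW", montage, eff, rng_seed=2)
        phase = connectivity.band_phase(ep, (8.0, 10.0))
        plv = connectivity.plv_from_phase(phase, guard_samples=250)
        i, j = montage.index("C3"), montage.index("C1")
        assert plv[i, j] == pytest.approx(1.0, abs=1e-6)

    def test_mw_low_alpha_power_exceeds_ont_at_fpz(self, montage):
        idx = montage.index("Fpz")
        grid = spectral.frequency_grid()
        sel = (grid >= 8.0) & (grid <= 10.0)
        means = {}
        for cond in ("onT", "MW"):
            p = [
                spectral.stft_power(
                    gen_eeg_epoch(cond, montage, rng_seed=1000 + i)[idx:idx + 1]
                )[0][0, sel].mean()
                for i in range(60)
            ]
            means[cond] = np.mean(p)
        assert means["MW"] > means["onT"]


class TestDataset:
    def test_default_trial_count(self, default_dataset):
        assert default_dataset.n_trials == 9 * 36
        assert len(default_dataset.participants) == 9

    def test_same_seed_identical(self):
        a = gen_dataset(2, 8, seed=11)
        b = gen_dataset(2, 8, seed=11)
        for ta, tb in zip(a.all_trials(), b.all_trials()):
            assert np.array_equal(ta.eeg, tb.eeg)
            assert np.array_equal(ta.force_output, tb.force_output)
            assert ta.rating == tb.rating

    def test_rating_correlates_with_force_error(self, small_dataset):
        ratings, be = [], []
        for t in small_dataset.all_trials():
            ratings.append(t.rating)
            be.append(behavior.trial_error(behavior.sliding_force_error(
                t.force_target, t.force_output)))
        assert np.corrcoef(ratings, be)[0, 1] > 0.0

    def test_target_pattern_consistent_across_trials(self, small_dataset):
        trials = list(small_dataset.all_trials())
        for t in trials[1:]:
            assert np.array_equal(t.force_target, trials[0].force_target)

    def test_labels_balanced_per_participant(self, small_dataset):
        for part in small_dataset.participants:
            labs = [t.condition_label for t in part.trials]
            assert labs.count("onT") == labs.count("MW") == len(labs) // 4

    def test_invalid_args_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_dataset(2, 4)
        with pytest.raises(ConfigurationError):
            gen_dataset(2, [8, 8, 8])
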