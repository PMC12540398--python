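"""Configuration objects for the force-control task and the synthetic effect model.

``TaskConfig`` describes the visuo-haptic tracking task geometry: a dot moving
at constant angular speed around an annulus whose width (the target force)
varies nonlinearly over each cycle, with the dot diameter linearly mapped from
the exerted force.  ``EffectConfig`` collects the condition-dependent effect
strengths that the synthetic-data generator injects so that every downstream
analysis stage has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and timing of the continuous force-control task.

    Parameters
    ----------
    k : float
        Dot-diameter scaling constant in mm/N.
    diameter_offset : float
        Dot-diameter intercept in mm.
    force_min, force_max : float
        Allowable force range in newtons.
    dot_speed : float
        Angular speed of the moving dot in deg/s.
    cycle_deg : float
        Angular extent of one target-force cycle in degrees.
    sample_rate : float
        Sampling rate of force and EEG streams in Hz.
    epoch_duration : float
        Length of one analysis epoch in seconds (the pre-probe window).
    probe_interval_range : tuple of float
        Min/max interval between thought probes in seconds.
    """

    k: float = 3.0
    diameter_offset: float = 0.5
    force_min: float = 0.5
    force_max: float = 3.17
    dot_speed: float = 20.0
    cycle_deg: float = 60.0
    sample_rate: float = 1000.0
    epoch_duration: float = 3.0
    probe_interval_range: tuple[float, float] = (40.0, 50.0)
    force_profile_exponent: float = 2.0

    def __post_init__(self) -> None:
        if not self.force_min < self.force_max:
            raise ConfigurationError(
                f"force_min ({self.force_min}) must be < force_max ({self.force_max})"
            )
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.dot_speed <= 0 or self.cycle_deg <= 0:
            raise ConfigurationError("dot_speed and cycle_deg must be positive")
        cycle_s = self.cycle_deg / self.dot_speed
        if abs(cycle_s - self.epoch_duration) > 1e-9:
            raise ConfigurationError(
                f"cycle_deg / dot_speed ({cycle_s} s) must equal epoch_duration "
                f"({self.epoch_duration} s)"
            )
        lo, hi = self.probe_interval_range
        if not 0 < lo <= hi:
            raise ConfigurationError("probe_interval_range must be 0 < lo <= hi")

    @property
    def n_samples(self) -> int:
        """Number of samples in one epoch."""
        return int(round(self.epoch_duration * self.sample_rate))

    @property
    def cycle_duration(self) -> float:
        """Duration of one target-force cycle in seconds."""
        return self.cycle_deg / self.dot_speed


@dataclass(frozen=True)
class EffectConfig:
    """Condition-dependent effect strengths injected by the generator.

    The defaults encode the qualitative effect directions the analysis is
    designed to detect: in mind-wandering (MW) epochs, low-alpha (8-10 Hz)
    power is elevated at frontal and posterior electrodes, harmonic
    alpha:theta peak ratios at PO3/PO4 are rarer, phase coupling within the
    left-central community and across designated community pairs is stronger,
    the frontal alpha envelope tracks the force error more weakly, and force
    errors themselves are larger.

    Attributes
    ----------
    alpha_power_gain_mw : float
        Multiplier (>= 1) on 8-10 Hz oscillator amplitude at the frontal and
        posterior effect electrodes in MW epochs.
    harmonic_prob_ont, harmonic_prob_mw : float
        Probability that a PO3/PO4 epoch draws an alpha peak at ~2.8x the
        theta peak, per condition.
    plv_coupling_mw : float
        Mixing weight in [0, 1] of a shared 8-10 Hz phase source injected
        into the coupled communities in MW epochs.
    mi_gain_ont, mi_gain_mw : float
        Modulation depth of the frontal (F1-F6) alpha envelope by the
        within-trial force-error series, per condition.  The on-task gain
        exceeding the MW gain encodes the observed effect direction.
    rating_slope : float
        Mean per-trial drift of self-reported off-task ratings (0-100 scale).
    error_rating_corr : float
        Weight in [0, 1] controlling how tightly the per-trial force-noise
        level follows the rating (1 = deterministic, 0 = independent).
    rating_noise_sd : float
        SD of Gaussian noise added to the rating drift, in rating points.
    force_noise_sd : float
        Baseline SD of the smoothed tracking-noise process, in newtons.
    force_noise_gain : float
        Relative increase of tracking-noise SD from a fully on-task to a
        fully mind-wandering trial.
    pink_exponent : float
        Spectral exponent of the 1/f^a EEG background.
    pink_rms : float
        RMS amplitude of the broadband background in microvolts.
    alpha_amp, theta_amp : float
        Baseline oscillator amplitudes in microvolts.
    """

    alpha_power_gain_mw: float = 1.5
    harmonic_prob_ont: float = 0.65
    harmonic_prob_mw: float = 0.35
    plv_coupling_mw: float = 0.45
    mi_gain_ont: float = 0.6
    mi_gain_mw: float = 0.15
    rating_slope: float = 1.2
    error_rating_corr: float = 0.7
    rating_noise_sd: float = 12.0
    force_noise_sd: float = 0.15
    force_noise_gain: float = 0.8
    pink_exponent: float = 1.0
    pink_rms: float = 5.0
    alpha_amp: float = 4.0
    theta_amp: float = 3.0

    def __post_init__(self) -> None:
        for name in ("harmonic_prob_ont", "harmonic_prob_mw", "plv_coupling_mw",
                     "error_rating_corr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.alpha_power_gain_mw < 1.0:
            raise ConfigurationError("alpha_power_gain_mw must be >= 1")
        if self.mi_gain_ont < self.mi_gain_mw:
            raise ConfigurationError(
                "mi_gain_ont must be >= mi_gain_mw (on-task coupling is the "
                "stronger one by construction)"
            )

    @classmethod
    def neutral(cls) -> "EffectConfig":
        """An effect configuration under which onT and MW epochs are
        statistically exchangeable (all condition effects switched off)."""
        return cls(
            alpha_power_gain_mw=1.0,
            harmonic_prob_ont=0.5,
            harmonic_prob_mw=0.5,
            plv_coupling_mw=0.0,
            mi_gain_ont=0.3,
            mi_gain_mw=0.3,
            error_rating_corr=0.0,
            force_noise_gain=0.0,
        )

    def with_(self, **kwargs) -> "EffectConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_SEED = 20251008
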