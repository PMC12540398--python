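"""Synthetic force-control datasets with known attentional-state structure.

The generator emulates the recorded structure of a continuous visuo-haptic
force-tracking experiment: per participant, a sequence of thought-probe
trials, each consisting of a 3-s, 64-channel EEG epoch (1 kHz), the target
and output force traces for the same window, and a 0-100 off-task rating.
Ratings drift upward across trials; trials in the top rating quartile carry
mind-wandering (MW) effects, trials in the bottom quartile on-task (onT)
effects, and intermediate trials blend linearly between the two.

Injected condition effects (see :class:`mwdecode.config.EffectConfig`):

* larger force-tracking noise on high-rating trials;
* elevated 8-10 Hz oscillator amplitude at frontal and posterior electrodes
  in MW epochs;
* harmonically related alpha/theta peak frequencies (alpha ~ 2.8x theta) at
  PO3/PO4, more probable in onT epochs;
* a shared alpha-band phase source mixed into the left-central community and
  its designated partner communities in MW epochs;
* modulation of the frontal (F1-F6) alpha envelope by the within-trial
  force-error series, stronger in onT epochs.

Every output is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import MW, ONT, quartile_label, sliding_force_error
from .config import DEFAULT_SEED, ConfigurationError, EffectConfig, TaskConfig
from .montage import (
    FRONTAL_ALPHA_ELECTRODES,
    HARMONIC_ELECTRODES,
    MI_ELECTRODES,
    POSTERIOR_ALPHA_ELECTRODES,
    Montage,
    default_montage,
)

#: Relative weight of the shared alpha-band source per community in MW epochs.
_COMMUNITY_SOURCE_WEIGHTS = {"LC": 1.2, "F": 0.6, "RC": 0.6, "PO": 0.45}

#: Amplitude (microvolts) of the shared source at unit coupling and weight.
_SOURCE_AMP = 4.0

_THETA_RANGE = (4.5, 5.8)
_ALPHA_RANGE = (8.7, 10.0)
_ALPHA_RANGE_FRONTAL = (7.8, 8.6)   # centred in the 7.2-8.8 Hz coupling band
_THETA_RANGE_HARMONIC = (4.3, 4.6)  # 2.8x maps into 12.0-12.9 Hz
_HARMONIC_RATIO = 2.8


@dataclass
class TrialRecord:
    """One pre-probe window: EEG epoch, force traces, and the probe rating."""

    participant_id: str
    trial_index: int
    rating: float
    eeg: np.ndarray            # (64, n_samples) microvolts, float32
    force_target: np.ndarray   # (n_samples,) newtons
    force_output: np.ndarray   # (n_samples,) newtons
    condition_label: str       # "onT" | "MW" | "unlabeled"
    probe_time_s: float = 0.0

    def __post_init__(self) -> None:
        if self.eeg.shape[0] != 64:
            raise ValueError("EEG epoch must have exactly 64 channel rows")
        if self.force_target.shape != self.force_output.shape or \
                self.force_target.shape[0] != self.eeg.shape[1]:
            raise ValueError("force traces must match the EEG time axis")
        if not 0.0 <= self.rating <= 100.0:
            raise ValueError(f"rating must be in [0, 100], got {self.rating}")


@dataclass
class ParticipantRecord:
    participant_id: str
    trials: list[TrialRecord]


@dataclass
class SyntheticDataset:
    """A full synthetic study: participants, their trials, and the configs."""

    participants: list[ParticipantRecord]
    task_config: TaskConfig
    effect_config: EffectConfig
    seed: int
    montage: Montage = field(default_factory=default_montage, repr=False)

    @property
    def n_trials(self) -> int:
        return sum(len(p.trials) for p in self.participants)

    def all_trials(self):
        for p in self.participants:
            yield from p.trials


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _condition_level(condition) -> float:
    """Map a condition to the effect-blend level in [0, 1]."""
    if isinstance(condition, str):
        if condition == ONT:
            return 0.0
        if condition == MW:
            return 1.0
        raise ValueError(f"condition must be 'onT' or 'MW', got {condition!r}")
    level = float(condition)
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"effect level must be in [0, 1], got {level}")
    return level


def gen_target_force(cfg: TaskConfig = TaskConfig()) -> np.ndarray:
    """The deterministic target-force profile of one epoch.

    A raised cosine taken to ``cfg.force_profile_exponent`` spanning the
    allowable force range over one cycle: smooth, periodic, and nonlinear
    in time.  Identical for every trial.
    """
    n = cfg.n_samples
    t = np.arange(n) / cfg.sample_rate
    phase = (1.0 - np.cos(2.0 * np.pi * t / cfg.cycle_duration)) / 2.0
    profile = phase ** cfg.force_profile_exponent
    return cfg.force_min + (cfg.force_max - cfg.force_min) * profile


def dot_diameter(force, cfg: TaskConfig = TaskConfig(), *,
                 check_range: bool = True):
    """Dot diameter (mm) for an exerted force (N): ``D = k * F + offset``."""
    force = np.asarray(force, dtype=float)
    if check_range and np.any((force < cfg.force_min) | (force > cfg.force_max)):
        raise ValueError(
            f"force outside allowable range [{cfg.force_min}, {cfg.force_max}] N"
        )
    d = cfg.k * force + cfg.diameter_offset
    return float(d) if d.ndim == 0 else d


def gen_ratings(n_trials: int, effect: EffectConfig = EffectConfig(),
                rng_seed=DEFAULT_SEED) -> np.ndarray:
    """Off-task ratings drifting upward across trials, clipped to [0, 100]."""
    if n_trials < 8:
        raise ValueError(f"need >= 8 trials for quartile labeling, got {n_trials}")
    rng = _as_rng(rng_seed)
    baseline = rng.uniform(15.0, 35.0)
    noise = rng.normal(0.0, effect.rating_noise_sd, size=n_trials) \
        if effect.rating_noise_sd > 0 else np.zeros(n_trials)
    r = baseline + effect.rating_slope * np.arange(n_trials) + noise
    return np.clip(r, 0.0, 100.0)


def _smoothed_noise(n: int, rng: np.random.Generator,
                    smooth_samples: float = 50.0) -> np.ndarray:
    """Unit-variance low-frequency noise emulating slow tracking error."""
    e = gaussian_filter1d(rng.standard_normal(n), smooth_samples, mode="reflect")
    sd = e.std()
    return e / sd if sd > 0 else e


def gen_output_force(target: np.ndarray, condition,
                     effect: EffectConfig = EffectConfig(),
                     rng_seed=DEFAULT_SEED,
                     cfg: TaskConfig = TaskConfig()) -> np.ndarray:
    """Simulated output-force trace for one trial.

    The output is the target plus smoothed Gaussian tracking noise whose SD
    grows with the mind-wandering level, then clipped to the allowable force
    range, so MW trials carry larger expected BE_NL-trial than onT trials.
    """
    level = _condition_level(condition)
    rng = _as_rng(rng_seed)
    target = np.asarray(target, dtype=float)
    sigma = effect.force_noise_sd * (1.0 + effect.force_noise_gain * level)
    out = target + sigma * _smoothed_noise(target.size, rng)
    return np.clip(out, cfg.force_min, cfg.force_max)


def _pink_noise(shape: tuple[int, int], exponent: float, rms: float,
                sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^a background noise, unit-RMS-scaled per channel."""
    n = shape[1]
    white = rng.standard_normal(shape)
    if rms == 0.0:
        return np.zeros(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate)
    f[0] = f[1]
    spec /= f ** (exponent / 2.0)
    x = np.fft.irfft(spec, n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def gen_eeg_epoch(condition, montage: Montage,
                  effect: EffectConfig = EffectConfig(),
                  force_error_series: np.ndarray | None = None,
                  rng_seed=DEFAULT_SEED,
                  cfg: TaskConfig = TaskConfig()) -> np.ndarray:
    """One synthetic 64-channel EEG epoch in microvolts.

    The epoch is a 1/f background plus per-channel theta and alpha
    oscillators with epoch-random frequencies and phases.  ``condition`` may
    be ``"onT"``, ``"MW"``, or a blend level in [0, 1]; all condition
    effects scale linearly with the level, and the random-draw layout is
    identical at every level so that epochs are exchangeable when the effect
    configuration is neutral.

    ``force_error_series`` (the windowed BE_NL values of the same trial)
    drives the frontal alpha-envelope modulation; without it the envelope is
    flat.
    """
    for name in ("LC", "F", "RC", "PO"):
        if name not in montage.communities:
            from .montage import MontageError
            raise MontageError(f"montage lacks required community {name!r}")
    level = _condition_level(condition)
    rng = _as_rng(rng_seed)
    n = cfg.n_samples
    n_ch = len(montage)
    t = np.arange(n) / cfg.sample_rate

    x = _pink_noise((n_ch, n), effect.pink_exponent, effect.pink_rms,
                    cfg.sample_rate, rng)

    # Oscillator parameters: drawn for every channel regardless of level.
    theta_f = rng.uniform(*_THETA_RANGE, size=n_ch)
    theta_phase = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
    theta_amp = effect.theta_amp * rng.uniform(0.8, 1.2, size=n_ch)
    alpha_f = rng.uniform(*_ALPHA_RANGE, size=n_ch)
    alpha_phase = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
    alpha_amp = effect.alpha_amp * rng.uniform(0.8, 1.2, size=n_ch)

    mi_idx = montage.indices(MI_ELECTRODES)
    alpha_f[mi_idx] = rng.uniform(*_ALPHA_RANGE_FRONTAL, size=mi_idx.size)

    # Harmonic alpha:theta structure at the designated posterior electrodes.
    harm_idx = montage.indices(HARMONIC_ELECTRODES)
    u_harm = rng.uniform(size=harm_idx.size)
    theta_harm = rng.uniform(*_THETA_RANGE_HARMONIC, size=harm_idx.size)
    p_harm = effect.harmonic_prob_ont + \
        (effect.harmonic_prob_mw - effect.harmonic_prob_ont) * level
    take = u_harm < p_harm
    theta_f[harm_idx[take]] = theta_harm[take]
    alpha_f[harm_idx[take]] = _HARMONIC_RATIO * theta_harm[take]

    # Condition-dependent low-alpha amplitude gain.
    gain_idx = montage.indices(FRONTAL_ALPHA_ELECTRODES +
                               POSTERIOR_ALPHA_ELECTRODES)
    alpha_amp[gain_idx] *= 1.0 + (effect.alpha_power_gain_mw - 1.0) * level

    x += theta_amp[:, None] * np.cos(
        2.0 * np.pi * theta_f[:, None] * t + theta_phase[:, None])

    # Frontal alpha envelope tracks the force-error series.
    envelope = np.ones((n_ch, 1))
    alpha = alpha_amp[:, None] * np.cos(
        2.0 * np.pi * alpha_f[:, None] * t + alpha_phase[:, None])
    if force_error_series is not None:
        fes = np.asarray(force_error_series, dtype=float)
        centers = (np.arange(fes.size) + 0.5) * (n / max(fes.size, 1))
        span = np.ptp(fes)
        e01 = (fes - fes.min()) / span if span > 0 else np.full_like(fes, 0.5)
        e_t = np.interp(np.arange(n), centers, e01)
        g = effect.mi_gain_ont + (effect.mi_gain_mw - effect.mi_gain_ont) * level
        env_mi = 1.0 + g * (e_t - e_t.mean())
        alpha[mi_idx] *= env_mi[None, :]
    x += envelope * alpha

    # Shared alpha-band phase source mixed into the coupled communities.
    src_f = rng.uniform(8.8, 9.6)
    src_phase = rng.uniform(0.0, 2.0 * np.pi)
    coupling = effect.plv_coupling_mw * level
    if coupling > 0.0:
        source = np.cos(2.0 * np.pi * src_f * t + src_phase)
        weights = np.zeros(n_ch)
        for comm, w in _COMMUNITY_SOURCE_WEIGHTS.items():
            weights[montage.community_indices(comm)] = w
        x += coupling * _SOURCE_AMP * weights[:, None] * source[None, :]

    return x.astype(np.float32)


def _effect_level_per_trial(ratings: np.ndarray) -> np.ndarray:
    """Blend level per trial from within-participant rating ranks.

    Bottom-quartile trials get level 0, top-quartile level 1, and the middle
    half ramps linearly, so quartile labels and injected effects agree by
    construction.
    """
    n = ratings.size
    order = np.lexsort((np.arange(n), ratings))
    ranks = np.empty(n)
    ranks[order] = np.arange(n)
    rank01 = ranks / max(n - 1, 1)
    return np.clip((rank01 - 0.25) / 0.5, 0.0, 1.0)


def gen_dataset(n_participants: int = 9,
                trials_per_participant: int | list[int] = 36,
                cfg: TaskConfig = TaskConfig(),
                effect: EffectConfig = EffectConfig(),
                seed: int = DEFAULT_SEED,
                montage: Montage | None = None) -> SyntheticDataset:
    """Generate a complete synthetic study, reproducible from the seed."""
    if n_participants < 1:
        raise ConfigurationError("n_participants must be positive")
    if isinstance(trials_per_participant, int):
        counts = [trials_per_participant] * n_participants
    else:
        counts = list(trials_per_participant)
        if len(counts) != n_participants:
            raise ConfigurationError(
                "trials_per_participant list must match n_participants")
    if any(c < 8 for c in counts):
        raise ConfigurationError("each participant needs >= 8 trials")
    if montage is None:
        montage = default_montage()

    target = gen_target_force(cfg)
    children = np.random.SeedSequence(seed).spawn(n_participants)
    participants: list[ParticipantRecord] = []
    for p_idx, (n_trials, ss) in enumerate(zip(counts, children)):
        rng = np.random.default_rng(ss)
        pid = f"P{p_idx + 1:02d}"
        ratings = gen_ratings(n_trials, effect, rng)
        labels = quartile_label(ratings).labels
        levels = _effect_level_per_trial(ratings)
        probe_times = np.cumsum(rng.uniform(*cfg.probe_interval_range,
                                            size=n_trials))
        trials: list[TrialRecord] = []
        for i in range(n_trials):
            mix = effect.error_rating_corr * levels[i] + \
                (1.0 - effect.error_rating_corr) * rng.uniform()
            sigma = effect.force_noise_sd * (1.0 + effect.force_noise_gain * mix)
            output = np.clip(
                target + sigma * _smoothed_noise(target.size, rng),
                cfg.force_min, cfg.force_max)
            fes = sliding_force_error(target, output,
                                      sample_rate=cfg.sample_rate)
            eeg = gen_eeg_epoch(levels[i], montage, effect, fes.values, rng,
                                cfg)
            trials.append(TrialRecord(
                participant_id=pid,
                trial_index=i,
                rating=float(ratings[i]),
                eeg=eeg,
                force_target=target.copy(),
                force_output=output,
                condition_label=str(labels[i]),
                probe_time_s=float(probe_times[i]),
            ))
        participants.append(ParticipantRecord(participant_id=pid,
                                              trials=trials))
    return SyntheticDataset(participants=participants, task_config=cfg,
                            effect_config=effect, seed=seed, montage=montage)
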