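"""Force-tracking error metrics, trend statistics, and attentional-state labels.

The behavioral readout of the task is the normalized squared tracking error

    BE_NL = sum((F_target - F_output)^2) / sum(F_target^2)

evaluated in 1-s sliding windows with 90% overlap, and its within-trial sum
``BE_NL-trial``.  Trials are labeled on-task (onT) or mind-wandering (MW) by
the per-participant quartiles of the self-reported off-task ratings, which by
construction yields balanced classes and hence a 50% chance level for any
downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ONT, MW, UNLABELED = "onT", "MW", "unlabeled"


class SizeError(ValueError):
    """Raised when an input series is too short or shapes disagree."""


@dataclass(frozen=True)
class ForceErrorSeries:
    """Windowed BE_NL values for one trial."""

    values: np.ndarray
    window_starts: np.ndarray
    window_length: int
    step: int


@dataclass(frozen=True)
class ConditionLabels:
    """Per-trial attentional-state labels derived from rating quartiles."""

    labels: np.ndarray          # array of {"onT", "MW", "unlabeled"}
    n_per_condition: int
    cutoff_low: float
    cutoff_high: float


def force_error(target: np.ndarray, output: np.ndarray) -> float:
    """Normalized squared tracking error of one window.

    Returns ``sum((target - output)^2) / sum(target^2)``; 0 for perfect
    tracking and 1 when the output is identically zero.
    """
    target = np.asarray(target, dtype=float)
    output = np.asarray(output, dtype=float)
    if target.shape != output.shape or target.size < 1:
        raise SizeError("target and output must be equal-length, nonempty series")
    denom = float(np.sum(target ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("target series is identically zero")
    return float(np.sum((target - output) ** 2) / denom)


def sliding_force_error(
    target: np.ndarray,
    output: np.ndarray,
    window_s: float = 1.0,
    overlap: float = 0.9,
    sample_rate: float = 1000.0,
) -> ForceErrorSeries:
    """BE_NL in sliding windows (default 1 s, 90% overlap).

    For a 3-s trial at 1 kHz this yields 21 windows, matching the STFT
    windowing used for the EEG power time courses.
    """
    target = np.asarray(target, dtype=float)
    output = np.asarray(output, dtype=float)
    if target.shape != output.shape:
        raise SizeError("target and output must have the same length")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    win = int(round(window_s * sample_rate))
    if target.size < win:
        raise SizeError(f"series length {target.size} < window {win}")
    step = int(round(win * (1.0 - overlap)))
    step = max(step, 1)
    starts = np.arange(0, target.size - win + 1, step)
    values = np.array(
        [force_error(target[s:s + win], output[s:s + win]) for s in starts]
    )
    return ForceErrorSeries(values=values, window_starts=starts,
                            window_length=win, step=step)


def trial_error(fes: ForceErrorSeries) -> float:
    """BE_NL-trial: the sum of windowed BE_NL values over one trial."""
    if fes.values.size == 0:
        raise SizeError("empty force-error series")
    return float(np.sum(fes.values))


def quartile_label(ratings: np.ndarray) -> ConditionLabels:
    """Label trials by per-participant rating quartiles.

    The floor(n/4) lowest-rated trials become onT, the floor(n/4)
    highest-rated become MW, and the middle trials stay unlabeled.  Ties are
    resolved by rating rank with trial index as the final tie-break, so the
    two classes are always exactly balanced.
    """
    ratings = np.asarray(ratings, dtype=float)
    n = ratings.size
    if n < 8:
        raise SizeError(f"need >= 8 trials for quartile labeling, got {n}")
    k = n // 4
    order = np.lexsort((np.arange(n), ratings))  # rating asc, trial index asc
    labels = np.full(n, UNLABELED, dtype=object)
    labels[order[:k]] = ONT
    labels[order[-k:]] = MW
    return ConditionLabels(
        labels=labels,
        n_per_condition=k,
        cutoff_low=float(ratings[order[k - 1]]),
        cutoff_high=float(ratings[order[-k]]),
    )


def trend_slope_test(values_per_participant: list[np.ndarray]):
    """Per-participant linear trend across trials, with a one-tailed test.

    Each participant's series is z-scored, an OLS slope against trial index
    is fit, and a one-tailed one-sample t-test asks whether the group-mean
    slope exceeds zero.  A participant with zero variance contributes a
    slope of exactly 0 (flagged).

    Returns
    -------
    slopes : ndarray
        One fitted slope per participant (z-score units per trial).
    t : float
        One-sample t statistic on the slopes, df = N - 1.
    p : float
        One-tailed p-value for slope > 0.
    """
    slopes = []
    for vals in values_per_participant:
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            raise SizeError("need >= 3 trials per participant for a trend fit")
        sd = vals.std()
        if sd == 0.0:
            slopes.append(0.0)
            continue
        z = (vals - vals.mean()) / sd
        x = np.arange(vals.size, dtype=float)
        slopes.append(float(np.polyfit(x, z, 1)[0]))
    slopes = np.asarray(slopes)
    if slopes.size < 2:
        raise SizeError("need >= 2 participants")
    if np.all(slopes == slopes[0]):
        # Degenerate: identical slopes. t is +/- inf unless all zero.
        if slopes[0] == 0.0:
            return slopes, 0.0, 0.5
        t = np.inf * np.sign(slopes[0])
        return slopes, float(t), 0.0 if slopes[0] > 0 else 1.0
    res = sps.ttest_1samp(slopes, 0.0, alternative="greater")
    return slopes, float(res.statistic), float(res.pvalue)


def paired_condition_test(values_ont: np.ndarray, values_mw: np.ndarray):
    """Paired t-test on per-participant condition means (two-tailed).

    Zero-variance differences are reported as a sign-carried infinite t with
    p = 0 rather than NaN, so a perfectly consistent shift is flagged rather
    than lost.

    Returns (t, p); the contrast is ``values_ont - values_mw``.
    """
    a = np.asarray(values_ont, dtype=float)
    b = np.asarray(values_mw, dtype=float)
    if a.shape != b.shape:
        raise SizeError("condition vectors must have equal length")
    if a.size < 2:
        raise SizeError("need >= 2 participants for a paired test")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return 0.0, 1.0
        return float(np.inf * np.sign(d[0])), 0.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
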