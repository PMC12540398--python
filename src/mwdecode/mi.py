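"""Mutual information between force error and EEG power time courses.

For each trial the within-trial force-error series (21 sliding-window BE_NL
values) and the EEG log-power time course at each (channel, frequency) —
computed with the identical 1-s/90%-overlap window scheme, so the two series
are index-aligned — are reduced to a plug-in histogram estimate of

    MI(X, Y) = H(X) + H(Y) - H(X, Y)      [bits]

With only 21 samples per trial the estimate carries a positive bias of
roughly (bins_x - 1)(bins_y - 1) / (2 n ln 2); the bias is identical across
conditions and cancels in every condition contrast.  Estimates are clipped
at zero.  Equal-width binning (4 bins, about the square-root rule for n=21)
is the default; rank (copula) binning is available and makes the estimate
exactly invariant under strictly monotone transforms of either series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

from .behavior import SizeError, sliding_force_error
from .spectral import stft_power


def _entropy_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _bin_indices(x: np.ndarray, bins: int, rank: bool) -> np.ndarray:
    """Bin index per sample of a 1-D series."""
    if rank:
        order = np.argsort(x, kind="stable")
        r = np.empty(x.size, dtype=float)
        r[order] = np.arange(x.size)
        return np.minimum((r * bins / x.size).astype(int), bins - 1)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=int)
    idx = ((x - lo) / (hi - lo) * bins).astype(int)
    return np.minimum(idx, bins - 1)


def _bin_indices_cols(y: np.ndarray, bins: int, rank: bool) -> np.ndarray:
    """Columnwise bin indices of an (n, m) array of m series."""
    if rank:
        r = np.argsort(np.argsort(y, axis=0, kind="stable"),
                       axis=0, kind="stable").astype(float)
        return np.minimum((r * bins / y.shape[0]).astype(int), bins - 1)
    lo = y.min(axis=0, keepdims=True)
    span = y.max(axis=0, keepdims=True) - lo
    span[span == 0] = 1.0
    idx = ((y - lo) / span * bins).astype(int)
    return np.minimum(idx, bins - 1)


def histogram_mi(x: np.ndarray, y: np.ndarray, bins: int = 4,
                 rank: bool = False) -> float:
    """Plug-in MI estimate (bits) from an equal-width 2-D histogram.

    A constant series carries no information: MI is 0 by definition there.
    The plug-in identity can go fractionally negative in floating point;
    the result is clipped at 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size or x.size < bins:
        raise SizeError(
            f"series must have equal length >= bins ({bins}), got "
            f"{x.size} and {y.size}")
    ix = _bin_indices(x, bins, rank)
    iy = _bin_indices(y, bins, rank)
    joint = np.bincount(ix * bins + iy, minlength=bins * bins).astype(float)
    hx = _entropy_bits(np.bincount(ix, minlength=bins).astype(float))
    hy = _entropy_bits(np.bincount(iy, minlength=bins).astype(float))
    return max(hx + hy - _entropy_bits(joint), 0.0)


def _mi_columns(x: np.ndarray, y_cols: np.ndarray, bins: int,
                rank: bool) -> np.ndarray:
    """MI (bits) of a fixed series x against each column of y_cols."""
    n, m = y_cols.shape
    ix = _bin_indices(x, bins, rank)
    iy = _bin_indices_cols(y_cols, bins, rank)
    col = np.arange(m)[None, :]
    joint = np.bincount(
        (col * bins * bins + ix[:, None] * bins + iy).ravel(),
        minlength=m * bins * bins).reshape(m, bins * bins).astype(float)
    ycnt = np.bincount((col * bins + iy).ravel(),
                       minlength=m * bins).reshape(m, bins).astype(float)
    hx = _entropy_bits(np.bincount(ix, minlength=bins).astype(float))
    hy = -(xlogy(ycnt / n, ycnt / n) / np.log(2)).sum(axis=1)
    hxy = -(xlogy(joint / n, joint / n) / np.log(2)).sum(axis=1)
    return np.maximum(hx + hy - hxy, 0.0)


@dataclass(frozen=True)
class MITensor:
    """MI values (bits) indexed (trial, channel, frequency)."""

    values: np.ndarray
    freqs: np.ndarray
    bins: int
    rank: bool


def mi_map(eeg: np.ndarray, force_target: np.ndarray,
           force_output: np.ndarray,
           freqs: np.ndarray, bins: int = 4, rank: bool = False,
           sample_rate: float = 1000.0,
           window_s: float = 1.0, overlap: float = 0.9) -> np.ndarray:
    """Per-(channel, frequency) MI between force error and EEG log power.

    Both series use the same sliding-window scheme, so X (the 21-point
    BE_NL series) and Y (the 21-point log-power time course) are aligned
    window for window.
    """
    fes = sliding_force_error(force_target, force_output, window_s, overlap,
                              sample_rate)
    power, _ = stft_power(eeg, window_s, overlap, sample_rate, freqs,
                          return_windows=True)
    # power: (channels, windows, freqs); align with the BE_NL windows.
    if power.shape[1] != fes.values.size:
        raise SizeError(
            f"window schemes mismatched: {power.shape[1]} EEG windows vs "
            f"{fes.values.size} force-error windows")
    logp = np.log(np.maximum(power, np.finfo(float).tiny))
    n_ch = logp.shape[0]
    return np.stack([
        _mi_columns(fes.values, logp[c], bins, rank) for c in range(n_ch)
    ])


def mi_tensor(trials, freqs: np.ndarray, bins: int = 4, rank: bool = False,
              sample_rate: float = 1000.0) -> MITensor:
    """MI maps for a sequence of trial records."""
    vals = [
        mi_map(t.eeg, t.force_target, t.force_output, freqs, bins, rank,
               sample_rate).astype(np.float32)
        for t in trials
    ]
    return MITensor(values=np.stack(vals), freqs=np.asarray(freqs),
                    bins=bins, rank=rank)
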