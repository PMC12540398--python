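"""STFT band power per trial and electrode.

Power spectra are estimated with 1-s Hann-tapered sliding windows and 90%
overlap (21 windows on a 3-s epoch), zero-padded to a 0.1 Hz grid spanning
2-45 Hz, and averaged over windows.  Band powers are extracted on the
standard five-band scheme and log-transformed; absolute scale cancels in all
condition contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft as sfft
from scipy.signal import get_window

from .behavior import SizeError

#: Canonical EEG frequency bands, [low, high) Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

GRID_LOW, GRID_HIGH, GRID_STEP = 2.0, 45.0, 0.1


def frequency_grid(low: float = GRID_LOW, high: float = GRID_HIGH,
                   step: float = GRID_STEP) -> np.ndarray:
    """The analysis frequency grid (default 2-45 Hz in 0.1 Hz steps)."""
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


@dataclass(frozen=True)
class PowerTensor:
    """Log-power values indexed (trial, channel, frequency)."""

    values: np.ndarray          # log(power), (trial, channel, frequency)
    freqs: np.ndarray
    window_s: float
    overlap: float


def _window_starts(n_samples: int, win: int, step: int) -> np.ndarray:
    return np.arange(0, n_samples - win + 1, step)


def stft_power(epoch: np.ndarray, window_s: float = 1.0, overlap: float = 0.9,
               sample_rate: float = 1000.0,
               freqs: np.ndarray | None = None,
               return_windows: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged one-sided power spectrum of a (channels, samples) epoch.

    Each window is Hann-tapered and zero-padded so the spectrum lands on the
    requested frequency grid (default 0.1 Hz spacing from a 1-s window).
    With ``return_windows`` the per-window power time course is returned
    instead of the time average, for power-envelope analyses.

    Returns
    -------
    power : ndarray
        (channels, freqs) mean power, or (channels, windows, freqs) when
        ``return_windows`` is set.  One-sided periodogram scaling.
    freqs : ndarray
        The frequency grid.
    """
    epoch = np.atleast_2d(np.asarray(epoch))
    win = int(round(window_s * sample_rate))
    if epoch.shape[1] < win:
        raise SizeError(f"epoch length {epoch.shape[1]} < window {win}")
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    if freqs is None:
        freqs = frequency_grid()
    freqs = np.asarray(freqs, dtype=float)
    step_hz = float(freqs[1] - freqs[0]) if freqs.size > 1 else GRID_STEP
    nfft = int(round(sample_rate / step_hz))
    step = max(int(round(win * (1.0 - overlap))), 1)

    taper = get_window("hann", win, fftbins=True)
    segs = sliding_window_view(epoch, win, axis=1)[:, ::step, :]
    if segs.dtype == np.float32:
        taper = taper.astype(np.float32)
    spec = sfft.rfft(segs * taper, n=nfft, axis=2)
    # One-sided periodogram density scaling.
    scale = 2.0 / (sample_rate * np.sum(taper ** 2))
    power = scale * np.abs(spec) ** 2
    idx = np.round(freqs / step_hz).astype(int)
    power = power[:, :, idx]
    if return_windows:
        return power, freqs
    return power.mean(axis=1), freqs


def power_tensor(epochs, window_s: float = 1.0, overlap: float = 0.9,
                 sample_rate: float = 1000.0,
                 freqs: np.ndarray | None = None) -> PowerTensor:
    """Log-power tensor over a sequence of (channels, samples) epochs."""
    if freqs is None:
        freqs = frequency_grid()
    vals = []
    for ep in epochs:
        p, _ = stft_power(ep, window_s, overlap, sample_rate, freqs)
        vals.append(np.log(p).astype(np.float32))
    return PowerTensor(values=np.stack(vals), freqs=np.asarray(freqs),
                       window_s=window_s, overlap=overlap)


def band_log_power(pt: PowerTensor, band: str | tuple[float, float]) -> np.ndarray:
    """Mean log-power over a band's grid frequencies, per (trial, channel)."""
    if isinstance(band, str):
        if band not in BANDS:
            raise KeyError(f"unknown band {band!r}; known: {sorted(BANDS)}")
        lo, hi = BANDS[band]
    else:
        lo, hi = band
    sel = (pt.freqs >= lo) & (pt.freqs < hi)
    if not sel.any():
        raise ValueError(f"band [{lo}, {hi}) does not intersect the grid")
    return pt.values[:, :, sel].mean(axis=2)


def condition_average(pt: PowerTensor, labels, conditions=("onT", "MW")) -> dict:
    """Per-condition mean (channel, frequency) log-power over trials."""
    labels = np.asarray(labels)
    out = {}
    for cond in conditions:
        sel = labels == cond
        if not sel.any():
            raise SizeError(f"no trials labeled {cond!r}")
        out[cond] = pt.values[sel].mean(axis=0)
    return out
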