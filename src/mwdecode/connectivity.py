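"""Phase-locking-value (PLV) connectivity and community summaries.

PLV between two channels is the magnitude of the time-averaged unit phasor
of their instantaneous phase difference: 1 for complete phase locking, and
~Rayleigh-distributed around sqrt(pi)/(2 sqrt(T)) for independent phases.
Phases come from a zero-phase band-pass filter followed by the analytic
signal; a guard interval is discarded at both epoch ends to suppress filter
transients.  Community connectivity averages PLV within or between the four
scalp communities (F, PO, LC, RC).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import butter, filtfilt, hilbert

from .config import ConfigurationError
from .montage import Montage

#: Default analysis band for condition contrasts (low alpha).
LOW_ALPHA = (8.0, 10.0)


def band_phase(epoch: np.ndarray, band: tuple[float, float],
               sample_rate: float = 1000.0) -> np.ndarray:
    """Instantaneous phase (rad) per channel after zero-phase band-pass."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    lo, hi = band
    nyq = sample_rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ConfigurationError(
            f"band ({lo}, {hi}) must lie strictly inside (0, {nyq}) Hz")
    b, a = butter(4, [lo / nyq, hi / nyq], btype="band")
    filtered = filtfilt(b, a, epoch, axis=1)
    return np.angle(hilbert(filtered, axis=1))


def plv_from_phase(phase: np.ndarray, guard_samples: int = 0) -> np.ndarray:
    """Symmetric (channels, channels) PLV matrix from a phase array."""
    if guard_samples > 0:
        phase = phase[:, guard_samples:-guard_samples]
    u = np.exp(1j * phase)
    n_t = phase.shape[1]
    plv = np.abs(u @ u.conj().T) / n_t
    np.fill_diagonal(plv, 1.0)
    return np.clip(plv, 0.0, 1.0)


def plv_matrix(epochs, band: tuple[float, float] = LOW_ALPHA,
               sample_rate: float = 1000.0,
               guard_s: float = 0.25,
               average: bool = True) -> np.ndarray:
    """PLV over one or more (channels, samples) epochs.

    Each epoch yields its own time-averaged PLV matrix; with ``average``
    the per-epoch matrices are averaged (the condition-mean estimator),
    otherwise the (epochs, channels, channels) stack is returned.
    """
    guard = int(round(guard_s * sample_rate))
    mats = []
    for ep in epochs:
        phase = band_phase(ep, band, sample_rate)
        mats.append(plv_from_phase(phase, guard))
    stack = np.stack(mats)
    return stack.mean(axis=0) if average else stack


@dataclass(frozen=True)
class CommunityConnectivity:
    """Mean PLV within and between the four scalp communities."""

    within: dict[str, float]
    between: dict[tuple[str, str], float]

    def as_dict(self) -> dict[str, float]:
        out = {name: v for name, v in self.within.items()}
        out.update({f"{a}-{b}": v for (a, b), v in self.between.items()})
        return out


def community_connectivity(plv: np.ndarray, montage: Montage,
                           order=("F", "LC", "RC", "PO")) -> CommunityConnectivity:
    """Within- and between-community mean PLV from one 64x64 matrix.

    Within-community means run over unordered intra-community pairs with the
    diagonal excluded; between-community means run over all cross pairs.
    """
    plv = np.asarray(plv)
    idx = {}
    for name in order:
        members = montage.community_indices(name)
        if members.size == 0:
            raise ConfigurationError(f"community {name!r} is empty")
        idx[name] = members
    within = {}
    for name, members in idx.items():
        pairs = np.array(list(combinations(members, 2)))
        within[name] = float(plv[pairs[:, 0], pairs[:, 1]].mean())
    between = {}
    for a, b in combinations(order, 2):
        sub = plv[np.ix_(idx[a], idx[b])]
        between[(a, b)] = float(sub.mean())
    return CommunityConnectivity(within=within, between=between)


def community_connectivity_trials(plv_stack: np.ndarray, montage: Montage,
                                  order=("F", "LC", "RC", "PO")) -> dict[str, np.ndarray]:
    """Community summaries per trial from an (epochs, ch, ch) PLV stack."""
    keys = list(order) + [f"{a}-{b}" for a, b in combinations(order, 2)]
    out = {k: [] for k in keys}
    for m in plv_stack:
        cc = community_connectivity(m, montage, order).as_dict()
        for k in keys:
            out[k].append(cc[k])
    return {k: np.asarray(v) for k, v in out.items()}
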