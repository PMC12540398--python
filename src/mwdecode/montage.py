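"""64-channel EEG montage: labels, positions, adjacency, and communities.

The montage follows the extended international 10-20 layout of a 64-channel
cap.  Electrode positions come from the standard 10-05 template shipped with
MNE-Python; 2-D coordinates are an azimuthal-equidistant projection of the
3-D positions (the conventional flattened "topomap" view).  Channel adjacency
is the Delaunay triangulation of the projected positions with overlong edges
removed, and four scalp communities are defined for network-level summaries:
frontal (F), parieto-occipital (PO), left central motor (LC) and right
central motor (RC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

#: The 64 channel labels, in fixed row order (anterior to posterior).
CHANNEL_LABELS: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2", "Iz",
)

#: Community membership (communities are disjoint; Cz and CPz unassigned).
COMMUNITIES: dict[str, tuple[str, ...]] = {
    "F": ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
          "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
          "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8"),
    "LC": ("T7", "C5", "C3", "C1", "TP7", "CP5", "CP3", "CP1"),
    "RC": ("C2", "C4", "C6", "T8", "CP2", "CP4", "CP6", "TP8"),
    "PO": ("P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
           "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
           "O1", "Oz", "O2", "Iz"),
}

#: Frontal electrodes where the MW low-alpha power increase is injected.
FRONTAL_ALPHA_ELECTRODES: tuple[str, ...] = (
    "Fpz", "Fz", "FCz", "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7",
    "FC1", "FC3", "FC5", "FT7", "Fp2", "AF8", "AF4", "F2", "F4", "F6",
    "F8", "FC2", "FC4", "FC6",
)

#: Posterior electrodes where the MW low-alpha power increase is injected.
POSTERIOR_ALPHA_ELECTRODES: tuple[str, ...] = (
    "POz", "Oz", "Pz", "TP7", "P7", "P5", "P3", "PO7", "PO5", "PO3",
    "TP8", "CP6", "P4", "P6", "P8", "PO4", "PO6", "PO8",
)

#: Electrodes carrying the harmonic alpha:theta ratio effect.
HARMONIC_ELECTRODES: tuple[str, ...] = ("PO3", "PO4")

#: Frontal electrodes carrying the neural-behavioral coupling effect.
MI_ELECTRODES: tuple[str, ...] = ("F1", "F3", "F5", "F2", "F4", "F6")


class MontageError(ValueError):
    """Raised for malformed montage definitions."""


@dataclass
class Montage:
    """Channel labels, projected positions, adjacency, and communities.

    Attributes
    ----------
    labels : list of str
        Channel names in data-row order.
    pos_3d : ndarray, shape (n, 3)
        Head-frame electrode positions in meters.
    pos_2d : ndarray, shape (n, 2)
        Azimuthal-equidistant projection of ``pos_3d``.
    adjacency : ndarray of bool, shape (n, n)
        Symmetric, irreflexive spatial neighbourhood.
    communities : dict
        Community name -> tuple of member labels.
    """

    labels: list[str]
    pos_3d: np.ndarray
    pos_2d: np.ndarray
    adjacency: np.ndarray
    communities: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.labels)
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (n, n):
            raise MontageError("adjacency shape must match channel count")
        if not np.array_equal(adj, adj.T):
            raise MontageError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise MontageError("adjacency must be irreflexive")
        self.adjacency = adj
        seen: set[str] = set()
        for name, members in self.communities.items():
            for ch in members:
                if ch not in self.labels:
                    raise MontageError(f"community {name}: unknown channel {ch}")
                if ch in seen:
                    raise MontageError(f"channel {ch} assigned to two communities")
                seen.add(ch)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Row index of a channel label."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise MontageError(f"unknown channel label: {label}") from None

    def indices(self, labels) -> np.ndarray:
        """Row indices of a sequence of channel labels."""
        return np.array([self.index(lb) for lb in labels], dtype=int)

    def community_indices(self, name: str) -> np.ndarray:
        """Row indices of the members of a community."""
        if name not in self.communities:
            raise MontageError(f"unknown community: {name}")
        return self.indices(self.communities[name])

    def community_of(self, label: str) -> str | None:
        """Community name of a channel, or None if unassigned."""
        for name, members in self.communities.items():
            if label in members:
                return name
        return None


def _azimuthal_projection(pos_3d: np.ndarray) -> np.ndarray:
    """Project 3-D electrode positions to the plane: radius proportional to
    the polar angle from the vertex, azimuth preserved."""
    x, y, z = pos_3d.T
    r = np.linalg.norm(pos_3d, axis=1)
    polar = np.arccos(np.clip(z / np.where(r > 0, r, 1.0), -1.0, 1.0))
    azimuth = np.arctan2(y, x)
    return np.column_stack([polar * np.cos(azimuth), polar * np.sin(azimuth)])


def delaunay_adjacency(pos_2d: np.ndarray, edge_cap: float = 1.8) -> np.ndarray:
    """Channel adjacency from a Delaunay triangulation of projected positions.

    Edges longer than ``edge_cap`` times the median triangulation edge length
    are dropped, which removes the spurious long edges along the convex hull.
    """
    tri = Delaunay(pos_2d)
    n = pos_2d.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edges.add((i, j))
    lengths = {e: np.linalg.norm(pos_2d[e[0]] - pos_2d[e[1]]) for e in edges}
    cap = edge_cap * float(np.median(list(lengths.values())))
    for (i, j), length in lengths.items():
        if length <= cap:
            adj[i, j] = adj[j, i] = True
    return adj


def default_montage() -> Montage:
    """The standard 64-channel montage used throughout the package."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos_map = std.get_positions()["ch_pos"]
    pos_3d = np.array([pos_map[lb] for lb in CHANNEL_LABELS])
    pos_2d = _azimuthal_projection(pos_3d)
    adjacency = delaunay_adjacency(pos_2d)
    return Montage(
        labels=list(CHANNEL_LABELS),
        pos_3d=pos_3d,
        pos_2d=pos_2d,
        adjacency=adjacency,
        communities=dict(COMMUNITIES),
    )
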