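"""Nonparametric statistics for channel x feature maps and PLV networks.

Condition contrasts are paired (within-participant), so the exact
permutation scheme is a per-participant condition swap — equivalently a
random sign flip of each participant's condition difference.  Cluster-based
permutation tests control the family-wise error over (channel, frequency)
or (channel, ratio-bin) maps: supra-threshold t-values of equal sign are
clustered under channel adjacency (and feature-axis contiguity), each
cluster scored by its summed t mass, and compared against the permutation
null of the maximal same-sign cluster mass.  The network-based variant does
the same on PLV edges, with components linked through shared electrodes.
All permutation p-values use the add-one convention (b + 1)/(m + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

from .behavior import SizeError
from .config import ConfigurationError


@dataclass(frozen=True)
class TMap:
    """Pointwise paired-t map over (channel, feature)."""

    t: np.ndarray
    df: int


@dataclass(frozen=True)
class Cluster:
    """A connected set of supra-threshold (channel, feature) points."""

    channels: np.ndarray
    features: np.ndarray
    mass: float
    sign: int
    p: float


@dataclass(frozen=True)
class EdgeComponent:
    """A connected set of supra-threshold edges (channel pairs)."""

    edges: np.ndarray        # (k, 2) channel index pairs
    size: int
    mass: float
    sign: int
    p: float


def _paired_t(diff: np.ndarray, axis: int = 0) -> np.ndarray:
    """Paired t along an axis, with zero-variance differences mapped to a
    signed infinity (or 0 when the constant difference is itself 0)."""
    n = diff.shape[axis]
    mean = diff.mean(axis=axis)
    sd = diff.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = sd == 0
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            t = np.where(degenerate, np.sign(mean) * np.inf, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    return t


def paired_t_map(feat_a: np.ndarray, feat_b: np.ndarray) -> TMap:
    """Pointwise paired t over participants; contrast is ``feat_a - feat_b``.

    Inputs are (participants, channel, feature) condition means.
    """
    a = np.asarray(feat_a, dtype=float)
    b = np.asarray(feat_b, dtype=float)
    if a.shape != b.shape:
        raise SizeError("condition arrays must have the same shape")
    if a.shape[0] < 2:
        raise SizeError("need >= 2 participants")
    return TMap(t=_paired_t(a - b), df=a.shape[0] - 1)


def _feature_components(mask: np.ndarray, adjacency: np.ndarray):
    """Connected components of True points in a (channel, feature) mask.

    Points are adjacent along the feature axis at neighbouring indices and
    across channels (same feature index) under the montage adjacency.
    Returns (labels array aligned with mask.ravel()[nodes], nodes).
    """
    n_ch, n_f = mask.shape
    nodes = np.flatnonzero(mask.ravel())
    if nodes.size == 0:
        return np.empty(0, dtype=int), nodes
    rank = -np.ones(n_ch * n_f, dtype=int)
    rank[nodes] = np.arange(nodes.size)

    rows, cols = [], []
    horiz = mask[:, :-1] & mask[:, 1:]
    c, f = np.nonzero(horiz)
    rows.append(c * n_f + f)
    cols.append(c * n_f + f + 1)
    ai, aj = np.nonzero(np.triu(adjacency, 1))
    if ai.size:
        both = mask[ai] & mask[aj]           # (edges, n_f)
        e, f = np.nonzero(both)
        rows.append(ai[e] * n_f + f)
        cols.append(aj[e] * n_f + f)
    rows = rank[np.concatenate(rows)] if rows else np.empty(0, int)
    cols = rank[np.concatenate(cols)] if cols else np.empty(0, int)
    graph = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(nodes.size, nodes.size))
    _, labels = connected_components(graph, directed=False)
    return labels, nodes


def _max_masses(t: np.ndarray, tcrit: float, adjacency: np.ndarray):
    """Largest positive and negative cluster masses of a t-map."""
    out = []
    for sign in (1, -1):
        mask = (sign * t) > tcrit
        labels, nodes = _feature_components(mask, adjacency)
        if nodes.size == 0:
            out.append(0.0)
            continue
        masses = np.bincount(labels, weights=t.ravel()[nodes])
        out.append(float(np.abs(masses).max()))
    return out[0], out[1]


def cluster_permutation(feat_a: np.ndarray, feat_b: np.ndarray,
                        adjacency: np.ndarray, n_perm: int = 1000,
                        cluster_alpha: float = 0.05,
                        rng_seed=0) -> list[Cluster]:
    """Cluster-based permutation test on paired (channel, feature) maps.

    ``cluster_alpha`` is the two-sided point-level threshold that defines
    supra-threshold t-values; the null is the maximal same-sign cluster
    mass over per-participant sign flips.  Returns every observed cluster
    with its permutation p-value (clusters of both signs; caller applies
    the per-tail significance threshold).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    a = np.asarray(feat_a, dtype=float)
    b = np.asarray(feat_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise SizeError("inputs must be (participants, channel, feature)")
    n_p, n_ch, n_f = a.shape
    if adjacency.shape != (n_ch, n_ch):
        raise ConfigurationError("adjacency inconsistent with channel count")
    d = a - b
    df = n_p - 1
    tcrit = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, df))
    t_obs = _paired_t(d)

    rng = np.random.default_rng(rng_seed)
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_p)
        t_perm = _paired_t(d * signs[:, None, None])
        null_pos[i], null_neg[i] = _max_masses(t_perm, tcrit, adjacency)

    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = (sign * t_obs) > tcrit
        labels, nodes = _feature_components(mask, adjacency)
        if nodes.size == 0:
            continue
        null = null_pos if sign > 0 else null_neg
        for lab in range(labels.max() + 1):
            members = nodes[labels == lab]
            mass = float(t_obs.ravel()[members].sum())
            p = (np.sum(null >= abs(mass)) + 1.0) / (n_perm + 1.0)
            clusters.append(Cluster(
                channels=members // n_f, features=members % n_f,
                mass=mass, sign=sign, p=float(p)))
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return clusters


def _edge_components(supra: np.ndarray, t_edges: np.ndarray):
    """Components of a supra-threshold edge mask via shared nodes."""
    n_ch = supra.shape[0]
    graph = sparse.coo_matrix(supra.astype(float))
    n_comp, labels = connected_components(graph, directed=False)
    comps = []
    iu, ju = np.nonzero(np.triu(supra, 1))
    for lab in range(n_comp):
        sel = labels[iu] == lab
        if not sel.any():
            continue
        edges = np.column_stack([iu[sel], ju[sel]])
        comps.append((edges, float(t_edges[iu[sel], ju[sel]].sum())))
    return comps


def nbs_edge_test(plv_a: np.ndarray, plv_b: np.ndarray,
                  edge_alpha: float = 0.001, n_perm: int = 1000,
                  statistic: str = "size", rng_seed=0) -> list[EdgeComponent]:
    """Network-based statistic on paired PLV matrices.

    ``plv_a``/``plv_b`` are (participants, ch, ch) symmetric matrices.
    Edges with two-sided paired-t p below ``edge_alpha`` are retained; the
    connected components of same-sign supra-threshold edges are scored by
    edge count (``statistic="size"``) or summed |t| (``"mass"``) against
    the permutation null of the maximal same-sign component score.
    """
    a = np.asarray(plv_a, dtype=float)
    b = np.asarray(plv_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3 or a.shape[1] != a.shape[2]:
        raise SizeError("inputs must be (participants, ch, ch) stacks")
    if statistic not in ("size", "mass"):
        raise ConfigurationError("statistic must be 'size' or 'mass'")
    n_p, n_ch, _ = a.shape
    d = a - b
    df = n_p - 1
    tcrit = float(sps.t.ppf(1.0 - edge_alpha / 2.0, df))

    def score(comps):
        if not comps:
            return 0.0
        if statistic == "size":
            return float(max(len(e) for e, _ in comps))
        return float(max(abs(m) for _, m in comps))

    def sided_components(t):
        out = {}
        for sign in (1, -1):
            supra = (sign * t) > tcrit
            np.fill_diagonal(supra, False)
            out[sign] = _edge_components(supra, t)
        return out

    t_obs = _paired_t(d)
    rng = np.random.default_rng(rng_seed)
    null = {1: np.empty(n_perm), -1: np.empty(n_perm)}
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_p)
        comps = sided_components(_paired_t(d * signs[:, None, None]))
        null[1][i] = score(comps[1])
        null[-1][i] = score(comps[-1])

    results: list[EdgeComponent] = []
    for sign, comps in sided_components(t_obs).items():
        for edges, mass in comps:
            s = float(len(edges)) if statistic == "size" else abs(mass)
            p = (np.sum(null[sign] >= s) + 1.0) / (n_perm + 1.0)
            results.append(EdgeComponent(edges=edges, size=len(edges),
                                         mass=mass, sign=sign, p=float(p)))
    results.sort(key=lambda c: (c.size, abs(c.mass)), reverse=True)
    return results


def rm_anova_2level(values_a: np.ndarray, values_b: np.ndarray):
    """One-way repeated-measures ANOVA with two levels.

    For two levels the F statistic is exactly the square of the paired t,
    with df = (1, n - 1).  Returns (F, (1, n - 1), p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SizeError("inputs must be equal-length 1-D paired observations")
    n = a.size
    if n < 2:
        raise SizeError("need >= 2 paired observations")
    t = float(_paired_t((a - b)[:, None])[0])
    f = t ** 2
    if np.isinf(f):
        return float("inf"), (1, n - 1), 0.0
    p = float(sps.f.sf(f, 1, n - 1))
    return f, (1, n - 1), p
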