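"""End-to-end orchestration: dataset -> feature tensors -> stats -> decoding.

This module wires the feature families together the way the analysis uses
them: extract per-trial tensors once, reduce them to participant-level
condition means for the statistical maps, select (or fix) the cluster-level
feature blocks, and hand a trials x features matrix to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import behavior, cfc, classify, connectivity, mi, spectral, stats
from .montage import (
    FRONTAL_ALPHA_ELECTRODES,
    HARMONIC_ELECTRODES,
    MI_ELECTRODES,
    POSTERIOR_ALPHA_ELECTRODES,
    Montage,
)
from .synth import SyntheticDataset

#: Frequency band (Hz) of the low-alpha power and PLV contrasts.
POWER_BAND = (8.0, 10.0)
#: Ratio-bin range carrying the harmonic-prevalence contrast.
RATIO_RANGE = (2.6, 3.0)
#: Frequency band (Hz) of the neural-behavioral coupling contrast.
MI_BAND = (7.2, 8.8)
#: Community summaries entering the PLV feature block.
PLV_COMMUNITIES = ("LC", "F-LC", "LC-RC", "RC-PO")


@dataclass
class TrialFeatures:
    """All per-trial feature tensors for one dataset."""

    participants: np.ndarray          # (T,) participant ids
    ratings: np.ndarray               # (T,)
    labels: np.ndarray                # (T,) "onT" | "MW" | "unlabeled"
    be_trial: np.ndarray              # (T,) BE_NL-trial
    power: spectral.PowerTensor       # (T, 64, 431) log power
    ratio: cfc.RatioDensityTensor     # (T, 64, 23)
    plv: np.ndarray                   # (T, 64, 64), low-alpha band
    plv_cc: dict[str, np.ndarray]     # community summaries, each (T,)
    mi: mi.MITensor                   # (T, 64, n_freqs)
    montage: Montage = field(repr=False, default=None)


def extract_features(ds: SyntheticDataset,
                     mi_freqs: np.ndarray | None = None,
                     mi_bins: int = 4,
                     plv_band: tuple[float, float] = POWER_BAND) -> TrialFeatures:
    """Compute every feature tensor for a dataset, one pass over trials."""
    cfg = ds.task_config
    fs = cfg.sample_rate
    if mi_freqs is None:
        mi_freqs = spectral.frequency_grid()
    trials = list(ds.all_trials())

    participants = np.array([t.participant_id for t in trials])
    ratings = np.array([t.rating for t in trials])
    labels = np.array([t.condition_label for t in trials], dtype=object)
    be_trial = np.array([
        behavior.trial_error(behavior.sliding_force_error(
            t.force_target, t.force_output, sample_rate=fs))
        for t in trials
    ])
    power = spectral.power_tensor((t.eeg for t in trials), sample_rate=fs)
    ratio = cfc.ratio_density_tensor((t.eeg for t in trials), sample_rate=fs)
    plv = connectivity.plv_matrix((t.eeg for t in trials), plv_band,
                                  sample_rate=fs, average=False)
    plv_cc = connectivity.community_connectivity_trials(plv, ds.montage)
    mit = mi.mi_tensor(trials, mi_freqs, bins=mi_bins, sample_rate=fs)
    return TrialFeatures(participants=participants, ratings=ratings,
                         labels=labels, be_trial=be_trial, power=power,
                         ratio=ratio, plv=plv, plv_cc=plv_cc, mi=mit,
                         montage=ds.montage)


def participant_condition_means(values: np.ndarray, labels: np.ndarray,
                                participants: np.ndarray):
    """Stack per-participant condition means: (P, ...) arrays for onT and MW."""
    pids = np.unique(participants)
    ont, mw = [], []
    for pid in pids:
        sel = participants == pid
        ont.append(values[sel & (labels == behavior.ONT)].mean(axis=0))
        mw.append(values[sel & (labels == behavior.MW)].mean(axis=0))
    return np.stack(ont), np.stack(mw), pids


def canonical_feature_blocks(feats: TrialFeatures) -> dict[str, np.ndarray]:
    """Cluster-reduced per-trial feature blocks at the canonical effect loci.

    The loci are the frontal/posterior low-alpha clusters (power), the
    2.6-3.0 ratio bins at PO3/PO4 (ratio), the four condition-sensitive
    community summaries (plv), and the frontal 7.2-8.8 Hz band (mi).  Using
    a fixed, label-independent reduction keeps the classifier free of
    selection leakage.
    """
    m = feats.montage
    fsel = (feats.power.freqs >= POWER_BAND[0]) & \
           (feats.power.freqs <= POWER_BAND[1])
    p_front = feats.power.values[:, m.indices(FRONTAL_ALPHA_ELECTRODES)][:, :, fsel]
    p_post = feats.power.values[:, m.indices(POSTERIOR_ALPHA_ELECTRODES)][:, :, fsel]
    power_block = np.column_stack([
        p_front.mean(axis=(1, 2)), p_post.mean(axis=(1, 2))])

    bins = feats.ratio.binning.band_slice(*RATIO_RANGE)
    ratio_block = feats.ratio.values[:, m.indices(HARMONIC_ELECTRODES)][:, :, bins] \
        .mean(axis=(1, 2))[:, None]

    plv_block = np.column_stack([feats.plv_cc[k] for k in PLV_COMMUNITIES])

    msel = (feats.mi.freqs >= MI_BAND[0]) & (feats.mi.freqs <= MI_BAND[1])
    mi_block = feats.mi.values[:, m.indices(MI_ELECTRODES)][:, :, msel] \
        .mean(axis=(1, 2))[:, None]

    return {"power": power_block, "ratio": ratio_block,
            "plv": plv_block, "mi": mi_block}


def effect_directions(feats: TrialFeatures) -> dict[str, float]:
    """The five signed condition contrasts, from participant-level means.

    Positive values mean the effect was recovered in the expected
    direction: MW > onT for low-alpha power, community PLV and force error;
    onT > MW for harmonic-ratio density and frontal MI.
    """
    blocks = canonical_feature_blocks(feats)
    out = {}

    def contrast(values, mw_minus_ont):
        ont, mw, _ = participant_condition_means(
            values, feats.labels, feats.participants)
        d = (mw - ont) if mw_minus_ont else (ont - mw)
        return float(np.mean(d))

    out["alpha_power_mw_gt_ont"] = contrast(
        blocks["power"].mean(axis=1), mw_minus_ont=True)
    out["harmonic_ratio_ont_gt_mw"] = contrast(
        blocks["ratio"][:, 0], mw_minus_ont=False)
    for i, name in enumerate(PLV_COMMUNITIES):
        out[f"plv_{name}_mw_gt_ont"] = contrast(
            blocks["plv"][:, i], mw_minus_ont=True)
    out["mi_frontal_ont_gt_mw"] = contrast(
        blocks["mi"][:, 0], mw_minus_ont=False)
    out["force_error_mw_gt_ont"] = contrast(feats.be_trial, mw_minus_ont=True)
    return out


def clusterwise_feature_blocks(feats: TrialFeatures,
                               participants_subset: np.ndarray | None = None,
                               n_perm: int = 200,
                               cluster_alpha: float = 0.05,
                               p_threshold: float = 0.025,
                               rng_seed: int = 0) -> dict[str, np.ndarray]:
    """Data-driven feature blocks from cluster-permutation selection.

    Cluster tests run on the participant-level condition means of the
    subset given (e.g. the training participants of a LOSO fold); each
    significant cluster is reduced to its per-trial mean over member
    points, for all trials.  Falls back to the canonical block when a
    family yields no significant cluster (so the layout stays nonempty).
    """
    sel = np.ones(feats.participants.size, dtype=bool)
    if participants_subset is not None:
        sel = np.isin(feats.participants, participants_subset)
    adjacency = feats.montage.adjacency
    canonical = canonical_feature_blocks(feats)
    blocks: dict[str, np.ndarray] = {}
    family_tensors = {
        "power": feats.power.values,
        "ratio": feats.ratio.values,
        "mi": feats.mi.values,
    }
    for name, tensor in family_tensors.items():
        ont, mw, _ = participant_condition_means(
            tensor[sel], feats.labels[sel], feats.participants[sel])
        clusters = stats.cluster_permutation(
            ont.astype(float), mw.astype(float), adjacency,
            n_perm=n_perm, cluster_alpha=cluster_alpha, rng_seed=rng_seed)
        cols = [
            tensor[:, c.channels, c.features].mean(axis=1)
            for c in clusters if c.p < p_threshold
        ]
        blocks[name] = np.column_stack(cols) if cols else canonical[name]
    blocks["plv"] = canonical["plv"]
    return blocks


def decode(feats: TrialFeatures, feature_spec=("power", "ratio", "plv", "mi"),
           cv: str = "loso", k: int = 5, rng_seed: int = 0,
           blocks: dict[str, np.ndarray] | None = None) -> classify.MetricsReport:
    """Train/evaluate the SVM on labeled trials under LOSO or k-fold CV."""
    if blocks is None:
        blocks = canonical_feature_blocks(feats)
    labeled = feats.labels != behavior.UNLABELED
    y = classify.labels_to_binary(feats.labels[labeled])
    sub_blocks = {k_: v[labeled] for k_, v in blocks.items()}
    fm = classify.assemble_features(sub_blocks, list(feature_spec), y,
                                    feats.participants[labeled])
    if cv == "loso":
        return classify.loso_cv(fm)
    if cv == "kfold":
        return classify.within_kfold_cv(fm, k=k, rng_seed=rng_seed)
    raise ValueError("cv must be 'loso' or 'kfold'")


def permuted_label_accuracy(feats: TrialFeatures,
                            feature_spec=("power", "ratio", "plv", "mi"),
                            n_permutations: int = 100,
                            rng_seed: int = 0) -> tuple[float, np.ndarray]:
    """Mean LOSO accuracy over within-participant label permutations.

    The null-distribution check behind the 50% chance level: labels are
    shuffled within each participant (class balance preserved), the LOSO
    pipeline is re-run, and accuracies averaged.

    Returns (mean accuracy %, per-permutation accuracies).
    """
    blocks = canonical_feature_blocks(feats)
    labeled = feats.labels != behavior.UNLABELED
    y = classify.labels_to_binary(feats.labels[labeled])
    parts = feats.participants[labeled]
    sub_blocks = {k_: v[labeled] for k_, v in blocks.items()}
    rng = np.random.default_rng(rng_seed)
    accs = np.empty(n_permutations)
    for i in range(n_permutations):
        y_perm = y.copy()
        for pid in np.unique(parts):
            sel = np.flatnonzero(parts == pid)
            y_perm[sel] = y[sel][rng.permutation(sel.size)]
        fm = classify.assemble_features(sub_blocks, list(feature_spec),
                                        y_perm, parts)
        accs[i] = classify.loso_cv(fm).mean["accuracy"]
    return float(accs.mean()), accs
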