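"""SVM-RBF decoding of attentional state under two cross-validation schemes.

Feature vectors are assembled from cluster-selected points of the four
feature families (spectral power, ratio density, PLV edges or community
summaries, MI), z-scored with the training fold's statistics (population
SD), and fed to an RBF-kernel SVM with C = 1 and gamma = 1 / n_features.
Mind-wandering (MW) is the positive class.  Leave-one-subject-out (LOSO)
evaluates cross-participant generalization; stratified 5-fold within each
participant evaluates within-participant decoding.  Because quartile
labeling balances the classes, chance accuracy is 50%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .behavior import MW, ONT, SizeError
from .config import ConfigurationError

POSITIVE = MW


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters (fixed, no search)."""

    C: float = 1.0
    gamma: str | float = "auto"   # "auto" = 1 / n_features

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigurationError("C must be positive")
        if not (self.gamma == "auto" or
                (isinstance(self.gamma, (int, float)) and self.gamma > 0)):
            raise ConfigurationError("gamma must be 'auto' or positive")


@dataclass
class FeatureMatrix:
    """Trials x features with labels and participant ids."""

    X: np.ndarray
    y: np.ndarray                  # 0 = onT, 1 = MW
    participants: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size \
                or self.y.size != self.participants.size:
            raise SizeError("X, y and participants must be row-aligned")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")


@dataclass
class MetricsReport:
    """Per-fold and aggregate classification metrics, in percent."""

    per_fold: list[dict]
    mean: dict[str, float]
    sd: dict[str, float]
    dropped_columns: list[int] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @staticmethod
    def aggregate(per_fold: list[dict], notes=None) -> "MetricsReport":
        keys = ("accuracy", "recall", "precision", "f1", "auc")
        mean, sd = {}, {}
        for k in keys:
            vals = np.array([f[k] for f in per_fold if f.get(k) is not None],
                            dtype=float)
            mean[k] = float(vals.mean()) if vals.size else float("nan")
            sd[k] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return MetricsReport(per_fold=per_fold, mean=mean, sd=sd,
                             notes=list(notes or []))


def labels_to_binary(condition_labels) -> np.ndarray:
    """Map {"onT", "MW"} labels to {0, 1}."""
    arr = np.asarray(condition_labels)
    out = np.full(arr.size, -1, dtype=int)
    out[arr == ONT] = 0
    out[arr == MW] = 1
    if (out < 0).any():
        raise ValueError("labels must be 'onT' or 'MW' (drop unlabeled trials)")
    return out


def assemble_features(blocks: dict[str, np.ndarray], spec: list[str],
                      y: np.ndarray, participants: np.ndarray) -> FeatureMatrix:
    """Concatenate named feature blocks in the declared order.

    ``blocks`` maps a block name to a (trials, k) array of cluster-reduced
    features; ``spec`` lists the blocks to use, in order.
    """
    if not spec:
        raise ConfigurationError("feature spec must be nonempty")
    cols, names = [], []
    for name in spec:
        if name not in blocks:
            raise ConfigurationError(f"missing feature block {name!r}")
        b = np.atleast_2d(np.asarray(blocks[name], dtype=float))
        if b.shape[0] != y.size:
            b = b.T
        cols.append(b)
        names.extend(f"{name}[{j}]" for j in range(b.shape[1]))
    X = np.hstack(cols)
    return FeatureMatrix(X=X, y=np.asarray(y), feature_names=names,
                         participants=np.asarray(participants))


def zscore_fit_apply(train: np.ndarray, test: np.ndarray):
    """Standardize with the training fold's mean and population SD.

    Zero-SD columns are dropped from both matrices (their indices are
    returned) rather than producing NaNs.

    Returns (train_std, test_std, dropped_column_indices).
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.shape[0] == 0:
        raise SizeError("empty training matrix")
    mean = train.mean(axis=0)
    sd = train.std(axis=0)            # population SD (divide by n)
    keep = sd > 0
    dropped = list(np.flatnonzero(~keep))
    tr = (train[:, keep] - mean[keep]) / sd[keep]
    te = (test[:, keep] - mean[keep]) / sd[keep]
    return tr, te, dropped


def svm_rbf(X: np.ndarray, y: np.ndarray,
            cfg: SVMConfig = SVMConfig()) -> SVC:
    """Fit the RBF-kernel SVM (C = 1, gamma = 1 / n_features)."""
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    model = SVC(C=cfg.C, kernel="rbf", gamma=cfg.gamma)
    model.fit(X, y)
    return model


def decision_scores(model: SVC, X: np.ndarray) -> np.ndarray:
    """Decision-function scores oriented so larger = more MW-like."""
    scores = model.decision_function(X)
    # sklearn orients the decision function toward classes_[1].
    return scores if model.classes_[1] == 1 else -scores


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    scores: np.ndarray | None = None) -> dict:
    """Accuracy, recall, precision, F1 and AUC in percent, MW positive.

    AUC is None on single-class truth (undefined); precision is None when
    nothing was predicted positive.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise SizeError("y_true and y_pred must align")
    tp = float(np.sum((y_pred == 1) & (y_true == 1)))
    fp = float(np.sum((y_pred == 1) & (y_true == 0)))
    fn = float(np.sum((y_pred == 0) & (y_true == 1)))
    acc = 100.0 * float(np.mean(y_pred == y_true))
    recall = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    precision = 100.0 * tp / (tp + fp) if (tp + fp) > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if (precision is not None or recall is not None) else None
    auc = None
    if scores is not None and np.unique(y_true).size == 2:
        auc = 100.0 * float(roc_auc_score(y_true, scores))
    return {"accuracy": acc, "recall": recall, "precision": precision,
            "f1": f1, "auc": auc}


def _fit_eval(X_tr, y_tr, X_te, y_te, cfg: SVMConfig) -> dict:
    X_tr, X_te, dropped = zscore_fit_apply(X_tr, X_te)
    model = svm_rbf(X_tr, y_tr, cfg)
    pred = model.predict(X_te)
    scores = decision_scores(model, X_te)
    m = compute_metrics(y_te, pred, scores)
    m["n_test"] = int(y_te.size)
    m["dropped_columns"] = dropped
    return m


def loso_cv(fm: FeatureMatrix, cfg: SVMConfig = SVMConfig()) -> MetricsReport:
    """Leave-one-subject-out cross-validation."""
    pids = np.unique(fm.participants)
    if pids.size < 2:
        raise SizeError("LOSO needs >= 2 participants")
    per_fold, notes = [], []
    for pid in pids:
        test = fm.participants == pid
        fold = _fit_eval(fm.X[~test], fm.y[~test], fm.X[test], fm.y[test], cfg)
        fold["participant"] = str(pid)
        if np.unique(fm.y[test]).size < 2:
            notes.append(f"fold {pid}: single-class test set, AUC undefined")
        per_fold.append(fold)
    return MetricsReport.aggregate(per_fold, notes)


def within_kfold_cv(fm: FeatureMatrix, k: int = 5,
                    cfg: SVMConfig = SVMConfig(),
                    rng_seed: int = 0) -> MetricsReport:
    """Stratified k-fold cross-validation within each participant.

    Metrics are computed per fold and aggregated over all participant-fold
    pairs (mean +/- SD).  If a participant has fewer trials than folds, k
    is reduced for that participant with a notice.
    """
    per_fold, notes = [], []
    for pid in np.unique(fm.participants):
        sel = fm.participants == pid
        Xp, yp = fm.X[sel], fm.y[sel]
        k_eff = min(k, int(np.bincount(yp, minlength=2).min()), yp.size)
        if k_eff < 2:
            notes.append(f"participant {pid}: too few trials, skipped")
            continue
        if k_eff < k:
            notes.append(f"participant {pid}: k reduced to {k_eff}")
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True,
                              random_state=rng_seed)
        for fold_i, (tr, te) in enumerate(skf.split(Xp, yp)):
            fold = _fit_eval(Xp[tr], yp[tr], Xp[te], yp[te], cfg)
            fold["participant"] = str(pid)
            fold["fold"] = fold_i
            per_fold.append(fold)
    if not per_fold:
        raise SizeError("no participant had enough trials for k-fold CV")
    return MetricsReport.aggregate(per_fold, notes)
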