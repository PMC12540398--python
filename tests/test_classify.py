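"""Feature assembly, standardization, SVM decoding, and metrics."""

import numpy as np
import pytest

from mwdecode.behavior import SizeError
from mwdecode.classify import (
    FeatureMatrix,
    SVMConfig,
    assemble_features,
    compute_metrics,
    decision_scores,
    loso_cv,
    svm_rbf,
    within_kfold_cv,
    zscore_fit_apply,
)
from mwdecode.config import ConfigurationError


def make_fm(X, y, parts):
    return FeatureMatrix(X=np.asarray(X, float), y=np.asarray(y),
                         participants=np.asarray(parts))


class TestAssembleFeatures:
    def test_single_point_block_passes_through(self):
        y = np.array([0, 1])
        blocks = {"power": np.array([[1.5], [2.5]])}
        fm = assemble_features(blocks, ["power"], y, np.array(["a", "a"]))
        assert np.array_equal(fm.X, [[1.5], [2.5]])

    def test_identical_tensors_give_identical_rows(self):
        blocks = {"power": np.array([[1.0, 2.0], [1.0, 2.0]]),
                  "mi": np.array([[3.0], [3.0]])}
        fm = assemble_features(blocks, ["power", "mi"], np.array([0, 1]),
                               np.array(["a", "a"]))
        assert np.array_equal(fm.X[0], fm.X[1])

    def test_declared_order_respected(self):
        blocks = {"a": np.array([[1.0]]), "b": np.array([[2.0]])}
        fm = assemble_features(blocks, ["b", "a"], np.array([1]),
                               np.array(["p"]))
        assert fm.X.tolist() == [[2.0, 1.0]]

    def test_missing_block_rejected(self):
        with pytest.raises(ConfigurationError):
            assemble_features({}, ["power"], np.array([0]), np.array(["a"]))


class TestZscore:
    def test_train_standardized_with_population_sd(self):
        tr, te, dropped = zscore_fit_apply(np.array([[1.0], [3.0]]),
                                           np.array([[2.0]]))
        assert tr.ravel().tolist() == [-1.0, 1.0]
        assert te.ravel().tolist() == [0.0]
        assert dropped == []

    def test_test_transformed_with_train_statistics(self, rng):
        train = rng.normal(5.0, 2.0, size=(50, 3))
        tr, te, _ = zscore_fit_apply(train, train)
        assert np.allclose(tr.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(te, tr)

    def test_constant_column_dropped(self):
        train = np.array([[1.0, 7.0], [2.0, 7.0]])
        tr, te, dropped = zscore_fit_apply(train, train)
        assert dropped == [1]
        assert tr.shape[1] == 1


class TestSvm:
    def test_separable_data_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)),
                       rng.normal(3, 0.3, (20, 2))])
        y = np.repeat([0, 1], 20)
        model = svm_rbf(X, y)
        assert (model.predict(X) == y).all()

    def test_scores_oriented_toward_mw(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 1)),
                       rng.normal(3, 0.3, (20, 1))])
        y = np.repeat([0, 1], 20)
        s = decision_scores(svm_rbf(X, y), X)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_gamma_tracks_feature_dimension(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(int)
        m1 = svm_rbf(X, y)
        m2 = svm_rbf(np.hstack([X, np.zeros((30, 4))]), y)
        assert m1._gamma == pytest.approx(2 * m2._gamma)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            svm_rbf(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestMetrics:
    def test_all_mw_predictions_on_balanced_set(self):
        y = np.repeat([0, 1], 10)
        pred = np.ones(20, dtype=int)
        m = compute_metrics(y, pred)
        assert m["accuracy"] == pytest.approx(50.0)
        assert m["recall"] == pytest.approx(100.0)
        assert m["precision"] == pytest.approx(50.0)

    def test_perfect_prediction(self):
        y = np.repeat([0, 1], 10)
        m = compute_metrics(y, y, scores=y.astype(float))
        for k in ("accuracy", "recall", "precision", "f1", "auc"):
            assert m[k] == pytest.approx(100.0)

    def test_random_scores_auc_near_chance(self, rng):
        y = rng.integers(0, 2, size=4000)
        m = compute_metrics(y, y, scores=rng.normal(size=4000))
        assert m["auc"] == pytest.approx(50.0, abs=3.0)

    def test_single_class_truth_has_no_auc(self):
        m = compute_metrics(np.ones(5, int), np.ones(5, int),
                            scores=np.arange(5.0))
        assert m["auc"] is None


class TestCrossValidation:
    @staticmethod
    def _fm(rng, n_parts=4, per_class=6, informative=True):
        X, y, parts = [], [], []
        for p in range(n_parts):
            for cls in (0, 1):
                mu = (2 * cls - 1) * (2.0 if informative else 0.0)
                X.append(rng.normal(mu, 1.0, (per_class, 3)))
                y.extend([cls] * per_class)
                parts.extend([f"P{p}"] * per_class)
        return make_fm(np.vstack(X), y, parts)

    def test_loso_has_one_fold_per_participant(self, rng):
        rep = loso_cv(self._fm(rng))
        assert len(rep.per_fold) == 4

    def test_leaked_label_feature_gives_perfect_accuracy(self, rng):
        fm = self._fm(rng, informative=False)
        X = np.hstack([fm.X, fm.y[:, None].astype(float)])
        rep = loso_cv(make_fm(X, fm.y, fm.participants))
        assert rep.mean["accuracy"] == pytest.approx(100.0)

    def test_loso_single_participant_rejected(self, rng):
        fm = self._fm(rng, n_parts=1)
        with pytest.raises(SizeError):
            loso_cv(fm)

    def test_kfold_fold_sizes_for_18_trials(self, rng):
        fm = self._fm(rng, n_parts=1, per_class=9)
        rep = within_kfold_cv(fm, k=5, rng_seed=0)
        sizes = sorted(f["n_test"] for f in rep.per_fold)
        assert sizes == [3, 3, 4, 4, 4]

    def test_kfold_same_seed_reproducible(self, rng):
        fm = self._fm(rng)
        r1 = within_kfold_cv(fm, k=3, rng_seed=5)
        r2 = within_kfold_cv(fm, k=3, rng_seed=5)
        assert r1.mean == r2.mean

    def test_kfold_reduces_k_when_trials_scarce(self, rng):
        fm = self._fm(rng, n_parts=2, per_class=3)
        rep = within_kfold_cv(fm, k=5, rng_seed=0)
        assert any("reduced" in n for n in rep.notes)

    def test_perfect_features_decode_perfectly(self, rng):
        rep = within_kfold_cv(self._fm(rng), k=3, rng_seed=1)
        assert rep.mean["accuracy"] > 95.0
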