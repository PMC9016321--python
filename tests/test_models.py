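"""Submodel training, strict threshold voting, and baselines."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

from burnout_ensemble.batching import BalancedBatch, make_random_batches
from burnout_ensemble.evaluation import DEFAULT_THRESHOLDS
from burnout_ensemble.features import FeatureMatrix
from burnout_ensemble.models import (
    EnsembleModel,
    TrainedSubmodel,
    ensemble_from_json,
    ensemble_predict,
    ensemble_to_json,
    train_baseline_unbalanced,
    train_baseline_undersampled,
    train_ensemble,
    train_submodel,
    vote_fractions,
)


def feature_matrix(X, labels, prefix="s"):
    X = sp.csr_matrix(np.asarray(X))
    ids = [f"{prefix}{i}" for i in range(X.shape[0])]
    return FeatureMatrix(X=X, sample_ids=ids, labels=np.asarray(labels))


def separable_features(n_per_class=20, n_features=5, rng=None):
    """Label 1 iff feature 0 is large: linearly separable by construction."""
    rng = rng or np.random.default_rng(0)
    X = rng.integers(0, 3, size=(2 * n_per_class, n_features))
    X[:n_per_class, 0] = 10
    X[n_per_class:, 0] = 0
    labels = [1] * n_per_class + [0] * n_per_class
    return feature_matrix(X, labels)


def batch_for(features):
    pos = [i for i, l in zip(features.sample_ids, features.labels) if l == 1]
    neg = [i for i, l in zip(features.sample_ids, features.labels) if l == 0]
    return BalancedBatch(minority_ids=pos, majority_ids=neg, name="b0")


class _FixedVotes:
    """Stub estimator casting a fixed vote per sample (for voting tests)."""

    def __init__(self, votes):
        self.votes = np.asarray(votes, dtype=int)

    def predict(self, X):
        assert X.shape[0] == len(self.votes)
        return self.votes


def stub_ensemble(vote_matrix, threshold=0.8):
    """One submodel per row of vote_matrix; columns are samples."""
    subs = [TrainedSubmodel(estimator=_FixedVotes(row)) for row in vote_matrix]
    return EnsembleModel(submodels=subs, threshold=threshold)


def brute_force_votes(vote_matrix, p):
    """Independent oracle: literal loop-and-count over submodel votes."""
    n = len(vote_matrix)
    out = []
    for j in range(len(vote_matrix[0])):
        count = sum(vote_matrix[i][j] for i in range(n))
        out.append(1 if count / n > p else 0)
    return out


class TestTrainSubmodel:
    def test_separable_batch_has_perfect_cv(self):
        features = separable_features()
        sub = train_submodel(batch_for(features), features, cv_folds=5, seed=0)
        assert all(m["accuracy"] == 1.0 for m in sub.cv_metrics)
        assert len(sub.cv_metrics) == 5

    def test_no_signal_cv_accuracy_near_half(self):
        """Random features independent of labels: CV accuracy ~ 0.5."""
        rng = np.random.default_rng(42)
        means = []
        for _ in range(200):
            X = rng.normal(size=(24, 6))
            fm = feature_matrix(X, [1] * 12 + [0] * 12)
            sub = train_submodel(batch_for(fm), fm, cv_folds=4, seed=0)
            means.append(sub.mean_cv_accuracy)
        grand = np.mean(means)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(grand - 0.5) <= 3 * se + 1e-9

    def test_deterministic(self):
        features = separable_features()
        a = train_submodel(batch_for(features), features, cv_folds=5, seed=3)
        b = train_submodel(batch_for(features), features, cv_folds=5, seed=3)
        assert a.cv_metrics == b.cv_metrics
        assert np.array_equal(a.predict(features.X), b.predict(features.X))

    def test_missing_feature_id_rejected(self):
        features = separable_features()
        bad = BalancedBatch(minority_ids=["ghost"], majority_ids=["s39"], name="bad")
        with pytest.raises(ValueError, match="ghost"):
            train_submodel(bad, features, cv_folds=2)


class TestVoting:
    def test_unanimous_fraction(self):
        ens = stub_ensemble([[1], [1], [1]])
        assert vote_fractions(ens, np.zeros((1, 2))).tolist() == [1.0]

    def test_counting_example(self):
        ens = stub_ensemble([[1], [1], [0], [0], [0]])
        assert vote_fractions(ens, np.zeros((1, 2))).tolist() == [0.4]
        assert vote_fractions(stub_ensemble([[1], [1], [1], [0], [0]]), np.zeros((1, 2))).tolist() == [0.6]

    def test_strict_boundary_four_of_five_at_08(self):
        ens = stub_ensemble([[1], [1], [1], [1], [0]])
        X = np.zeros((1, 2))
        assert ensemble_predict(ens, X, p=0.8).tolist() == [0]
        assert ensemble_predict(ens, X, p=0.79).tolist() == [1]

    def test_p_zero_is_logical_or(self):
        votes = [[0, 1, 0], [0, 0, 0], [0, 1, 1]]
        ens = stub_ensemble(votes)
        assert ensemble_predict(ens, np.zeros((3, 2)), p=0.0).tolist() == [0, 1, 1]

    def test_invalid_threshold_rejected(self):
        ens = stub_ensemble([[1]])
        for p in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                ensemble_predict(ens, np.zeros((1, 2)), p=p)

    @pytest.mark.parametrize("n", range(1, 8))
    def test_matches_bruteforce_for_all_patterns(self, n):
        X = np.zeros((1, 2))
        for pattern in itertools.product([0, 1], repeat=n):
            ens = stub_ensemble([[v] for v in pattern])
            for p in DEFAULT_THRESHOLDS:
                expected = brute_force_votes([[v] for v in pattern], p)
                assert ensemble_predict(ens, X, p=p).tolist() == expected

    def test_positive_set_shrinks_as_threshold_grows(self):
        rng = np.random.default_rng(5)
        votes = rng.integers(0, 2, size=(7, 40))
        ens = stub_ensemble(votes)
        X = np.zeros((40, 2))
        prev = None
        for p in sorted(DEFAULT_THRESHOLDS):
            pos = set(np.flatnonzero(ensemble_predict(ens, X, p=p)))
            if prev is not None:
                assert pos <= prev
            prev = pos

    def test_identical_submodels_equal_single_submodel(self):
        votes = [0, 1, 1, 0]
        ens = stub_ensemble([votes] * 6)
        X = np.zeros((4, 2))
        for p in DEFAULT_THRESHOLDS:
            assert ensemble_predict(ens, X, p=p).tolist() == votes

    def test_single_submodel_ensemble_reproduces_it(self):
        features = separable_features()
        sub = train_submodel(batch_for(features), features, cv_folds=5, seed=0)
        ens = EnsembleModel(submodels=[sub], threshold=0.5)
        assert np.array_equal(
            ensemble_predict(ens, features.X, p=0.5), sub.predict(features.X)
        )


class TestBaselines:
    def test_unbalanced_baseline_perfect_on_separable(self):
        features = separable_features()
        model = train_baseline_unbalanced(features)
        assert np.array_equal(model.predict(features.X), features.labels)

    def test_single_class_rejected(self):
        fm = feature_matrix(np.eye(4), [0, 0, 0, 0])
        with pytest.raises(ValueError, match="single class"):
            train_baseline_unbalanced(fm)

    def test_undersampled_baseline_uses_balanced_training_set(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 4, size=(60, 6))
        fm = feature_matrix(X, [1] * 12 + [0] * 48)
        model = train_baseline_undersampled(fm, seed=2, cv_folds=4)
        # 12 positives + 12 sampled controls -> folds cover 24 samples
        assert sum(1 for _ in model.cv_metrics) == 4
        again = train_baseline_undersampled(fm, seed=2, cv_folds=4)
        assert np.array_equal(model.predict(fm.X), again.predict(fm.X))


def test_ensemble_json_roundtrip(tmp_path):
    features = separable_features()
    pos = [i for i, l in zip(features.sample_ids, features.labels) if l == 1]
    neg = [i for i, l in zip(features.sample_ids, features.labels) if l == 0]
    batches = make_random_batches(pos[:10], neg, n_batches=2, seed=0)
    ens = train_ensemble(batches, features, cv_folds=5, seed=0)
    ensemble_to_json(ens, tmp_path / "m.json")
    back = ensemble_from_json(tmp_path / "m.json")
    assert back.n_submodels == 2
    assert np.array_equal(
        ensemble_predict(back, features.X, p=0.5), ensemble_predict(ens, features.X, p=0.5)
    )
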