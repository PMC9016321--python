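"""Confusion-derived metrics, submodel statistics, threshold sweeps."""

import math

import numpy as np
import pytest
from sklearn.metrics import balanced_accuracy_score, f1_score

from burnout_ensemble.evaluation import (
    ConfusionMatrix,
    accuracy,
    balanced_accuracy,
    confusion,
    evaluate_model,
    f1_scores,
    metrics_from_confusion,
    submodel_statistics,
    sweep_thresholds,
)
from burnout_ensemble.models import EnsembleModel, TrainedSubmodel

from test_models import _FixedVotes, stub_ensemble


class TestConfusion:
    def test_hand_count(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_predictor(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fp == cm.fn == 0

    def test_constant_negative_predictor(self):
        cm = confusion([1] * 3 + [0] * 7, [0] * 10)
        assert (cm.fn, cm.tn, cm.tp, cm.fp) == (3, 7, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_all_majority_predictor_scores_half(self):
        cm = confusion([1] * 5 + [0] * 95, [0] * 100)
        assert balanced_accuracy(cm) == 0.5
        assert f1_scores(cm)[0] == 0.0

    def test_perfect_predictor_scores_one(self):
        cm = confusion([1, 0, 1, 0], [1, 0, 1, 0])
        assert balanced_accuracy(cm) == 1.0
        assert f1_scores(cm) == (1.0, 1.0)

    def test_balanced_accuracy_arithmetic(self):
        cm = ConfusionMatrix(tp=50, fn=50, tn=75, fp=25)
        assert balanced_accuracy(cm) == pytest.approx(0.625)

    def test_empty_class_undefined(self):
        with pytest.raises(ValueError, match="lacks a class"):
            balanced_accuracy(ConfusionMatrix(tp=0, fn=0, tn=5, fp=1))

    def test_f1_pos_symmetric_case(self):
        assert f1_scores(ConfusionMatrix(tp=1, fp=1, tn=1, fn=1))[0] == pytest.approx(0.5)

    def test_degenerate_f1_is_zero(self):
        assert f1_scores(ConfusionMatrix(tp=0, fp=0, tn=4, fn=0)) == (0.0, 0.5)

    def test_agreement_with_reference_implementation(self):
        """Dual route: our closed-form metrics vs scikit-learn on random labels."""
        rng = np.random.default_rng(3)
        for _ in range(25):
            y = rng.integers(0, 2, size=50)
            yhat = rng.integers(0, 2, size=50)
            if len(set(y)) < 2:
                continue
            cm = confusion(y, yhat)
            assert balanced_accuracy(cm) == pytest.approx(balanced_accuracy_score(y, yhat))
            f1_pos, f1_macro = f1_scores(cm)
            assert f1_pos == pytest.approx(f1_score(y, yhat, zero_division=0))
            assert f1_macro == pytest.approx(
                f1_score(y, yhat, average="macro", zero_division=0)
            )

    def test_accuracy_equals_balanced_accuracy_on_balanced_truth(self):
        rng = np.random.default_rng(8)
        y = np.array([1] * 30 + [0] * 30)
        yhat = rng.integers(0, 2, size=60)
        cm = confusion(y, yhat)
        assert accuracy(cm) == pytest.approx(balanced_accuracy(cm))


class TestSubmodelStats:
    def _labels(self):
        return np.array([1] * 10 + [0] * 10)

    def _features(self):
        import scipy.sparse as sp

        from burnout_ensemble.features import FeatureMatrix

        return FeatureMatrix(
            X=sp.csr_matrix(np.zeros((20, 2))),
            sample_ids=[f"s{i}" for i in range(20)],
            labels=self._labels(),
        )

    def _sub(self, votes):
        return TrainedSubmodel(estimator=_FixedVotes(votes))

    def test_recall_mean_and_sample_sd(self):
        # submodel A: recall 0.8 on 10 positives; submodel B: recall 1.0
        a = self._sub([1] * 8 + [0] * 2 + [0] * 10)
        b = self._sub([1] * 10 + [0] * 10)
        ens = EnsembleModel(submodels=[a, b], threshold=0.5)
        stats = submodel_statistics(ens, self._features())
        mean, sd = stats.test_recall
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(0.14142, abs=1e-4)

    def test_identical_submodels_have_zero_sd(self):
        votes = [1] * 5 + [0] * 15
        ens = EnsembleModel(submodels=[self._sub(votes)] * 3, threshold=0.5)
        stats = submodel_statistics(ens, self._features())
        assert stats.test_recall[1] == pytest.approx(0.0)
        assert stats.test_balanced_accuracy[1] == pytest.approx(0.0)

    def test_means_invariant_to_order(self):
        a = self._sub([1] * 8 + [0] * 12)
        b = self._sub([1] * 10 + [0] * 10)
        fwd = submodel_statistics(EnsembleModel(submodels=[a, b], threshold=0.5), self._features())
        rev = submodel_statistics(EnsembleModel(submodels=[b, a], threshold=0.5), self._features())
        assert fwd.test_recall == rev.test_recall

    def test_single_submodel_sd_undefined(self):
        ens = EnsembleModel(submodels=[self._sub([1] * 10 + [0] * 10)], threshold=0.5)
        stats = submodel_statistics(ens, self._features())
        assert math.isnan(stats.test_recall[1])


class TestSweep:
    def _setup(self):
        rng = np.random.default_rng(6)
        votes = rng.integers(0, 2, size=(9, 60))
        labels = np.array([1] * 12 + [0] * 48)
        import scipy.sparse as sp

        from burnout_ensemble.features import FeatureMatrix

        fm = FeatureMatrix(
            X=sp.csr_matrix(np.zeros((60, 2))),
            sample_ids=[f"s{i}" for i in range(60)],
            labels=labels,
        )
        return stub_ensemble(votes), fm

    def test_threshold_zero_matches_or_predictor(self):
        ens, fm = self._setup()
        sweep = sweep_thresholds(ens, fm, ps=[0.0])
        or_votes = (np.array([s.estimator.votes for s in ens.submodels]).sum(axis=0) > 0).astype(int)
        expected = metrics_from_confusion(confusion(fm.labels, or_votes))
        assert sweep.reports[0.0] == expected

    def test_recall_and_fp_non_increasing(self):
        ens, fm = self._setup()
        sweep = sweep_thresholds(ens, fm)
        recalls = sweep.metric_series("recall_pos")
        fps = sweep.fp_series()
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))
        assert all(a >= b for a, b in zip(fps, fps[1:]))

    def test_sweep_deterministic(self):
        ens, fm = self._setup()
        a = sweep_thresholds(ens, fm)
        b = sweep_thresholds(ens, fm)
        assert a == b

    def test_invalid_threshold_rejected(self):
        ens, fm = self._setup()
        with pytest.raises(ValueError):
            sweep_thresholds(ens, fm, ps=[0.5, 1.0])

    def test_csv_export(self, tmp_path):
        ens, fm = self._setup()
        sweep = sweep_thresholds(ens, fm, ps=[0.4, 0.8])
        sweep.write_csv(tmp_path / "s.csv")
        lines = (tmp_path / "s.csv").read_text().strip().splitlines()
        assert lines[0] == "threshold,metric,value"
        assert len(lines) == 1 + 2 * 6


def test_evaluate_model_routes_ensemble_and_submodel():
    import scipy.sparse as sp

    from burnout_ensemble.features import FeatureMatrix

    labels = np.array([1, 1, 0, 0])
    fm = FeatureMatrix(
        X=sp.csr_matrix(np.zeros((4, 2))), sample_ids=list("abcd"), labels=labels
    )
    sub = TrainedSubmodel(estimator=_FixedVotes([1, 0, 0, 1]))
    report = evaluate_model(sub, fm)
    assert report.confusion.tp == 1 and report.confusion.fp == 1
    ens = EnsembleModel(submodels=[sub], threshold=0.5)
    assert evaluate_model(ens, fm, p=0.5) == report
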