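"""Confusion-derived metrics, submodel statistics, and threshold sweeps.

On a heavily imbalanced test set, plain accuracy is dominated by the
majority class (a constant all-majority predictor scores ~97% on a 2.6%-
prevalence corpus), so balanced accuracy — the mean of the two per-class
recalls — is the headline metric, alongside positive-class recall (the
screening priority) and both F1 variants.  Positive-class and macro F1
are always reported side by side and explicitly labeled.

A threshold sweep computes one metrics report per voting threshold from
a single set of vote fractions; no submodel is ever refit during a
sweep.  Strict-majority voting makes the positive-prediction set shrink
as the threshold grows, so recall and false-positive counts are monotone
non-increasing across a sweep — this is asserted as a data invariant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FeatureMatrix
from .models import EnsembleModel, TrainedSubmodel, ensemble_predict, vote_fractions

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ConfusionMatrix",
    "MetricsReport",
    "SubmodelStats",
    "SweepResult",
    "confusion",
    "accuracy",
    "balanced_accuracy",
    "f1_scores",
    "metrics_from_confusion",
    "evaluate_model",
    "submodel_statistics",
    "sweep_thresholds",
]

#: Voting thresholds evaluated in the standard sweep.
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; the positive class is label 1."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def confusion(true_labels, predicted_labels) -> ConfusionMatrix:
    """Count tp/fp/tn/fn for binary labels (positive = 1)."""
    y = np.asarray(true_labels, dtype=int)
    yhat = np.asarray(predicted_labels, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError(f"label length mismatch: {y.shape} vs {yhat.shape}")
    bad = set(np.unique(y)) | set(np.unique(yhat))
    if not bad <= {0, 1}:
        raise ValueError(f"labels must be 0/1, found {sorted(bad - {0, 1})}")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Mean of per-class recalls: (tp/(tp+fn) + tn/(tn+fp)) / 2.

    Raises
    ------
    ValueError
        If either class is absent — balanced accuracy is undefined on a
        single-class evaluation set.
    """
    if cm.n_positive == 0 or cm.n_negative == 0:
        raise ValueError(
            "balanced accuracy undefined: evaluation set lacks a class "
            f"(positives={cm.n_positive}, negatives={cm.n_negative})"
        )
    return (cm.tp / cm.n_positive + cm.tn / cm.n_negative) / 2


def f1_scores(cm: ConfusionMatrix) -> tuple[float, float]:
    """Return (positive-class F1, macro F1); degenerate denominators give 0."""
    denom_pos = 2 * cm.tp + cm.fp + cm.fn
    f1_pos = 2 * cm.tp / denom_pos if denom_pos else 0.0
    denom_neg = 2 * cm.tn + cm.fn + cm.fp
    f1_neg = 2 * cm.tn / denom_neg if denom_neg else 0.0
    return f1_pos, (f1_pos + f1_neg) / 2


@dataclass
class MetricsReport:
    """All headline metrics for one model on one evaluation set."""

    accuracy: float
    balanced_accuracy: float
    recall_pos: float
    f1_pos: float
    f1_macro: float
    confusion: ConfusionMatrix

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "recall_pos": self.recall_pos,
            "f1_pos": self.f1_pos,
            "f1_macro": self.f1_macro,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
        }


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    f1_pos, f1_macro = f1_scores(cm)
    return MetricsReport(
        accuracy=accuracy(cm),
        balanced_accuracy=balanced_accuracy(cm),
        recall_pos=cm.tp / cm.n_positive,
        f1_pos=f1_pos,
        f1_macro=f1_macro,
        confusion=cm,
    )


def evaluate_model(
    model: TrainedSubmodel | EnsembleModel,
    test_features: FeatureMatrix,
    test_labels=None,
    p: float | None = None,
) -> MetricsReport:
    """Predict on the test set and compute the full metrics report.

    ``p`` (the voting threshold) applies only to ensembles; a plain
    submodel ignores it.
    """
    labels = test_features.labels if test_labels is None else np.asarray(test_labels, dtype=int)
    if isinstance(model, EnsembleModel):
        pred = ensemble_predict(model, test_features, p=p)
    else:
        pred = model.predict(test_features.X)
    return metrics_from_confusion(confusion(labels, pred))


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return mean, sd


@dataclass
class SubmodelStats:
    """Mean and sample SD (n-1) of per-submodel metrics across an ensemble."""

    cv_accuracy: tuple[float, float]
    cv_f1_macro: tuple[float, float]
    test_balanced_accuracy: tuple[float, float]
    test_f1_pos: tuple[float, float]
    test_f1_macro: tuple[float, float]
    test_recall: tuple[float, float]
    n_submodels: int = 0

    def to_dict(self) -> dict:
        def pair(t):
            return {"mean": t[0], "sd": None if math.isnan(t[1]) else t[1]}

        return {
            "n_submodels": self.n_submodels,
            "cv_accuracy": pair(self.cv_accuracy),
            "cv_f1_macro": pair(self.cv_f1_macro),
            "test_balanced_accuracy": pair(self.test_balanced_accuracy),
            "test_f1_pos": pair(self.test_f1_pos),
            "test_f1_macro": pair(self.test_f1_macro),
            "test_recall": pair(self.test_recall),
        }


def submodel_statistics(
    ensemble: EnsembleModel, test_features: FeatureMatrix, test_labels=None
) -> SubmodelStats:
    """Evaluate each submodel individually and aggregate across them.

    SDs use the n-1 denominator; with a single submodel they are
    reported as undefined (NaN).  Means are invariant to submodel order.
    """
    labels = test_features.labels if test_labels is None else np.asarray(test_labels, dtype=int)
    cv_acc, cv_f1, bals, f1ps, f1ms, recalls = [], [], [], [], [], []
    for sub in ensemble.submodels:
        cv_acc.append(sub.mean_cv_accuracy)
        cv_f1.append(sub.mean_cv_f1_macro)
        cm = confusion(labels, sub.predict(test_features.X))
        f1_pos, f1_macro = f1_scores(cm)
        bals.append(balanced_accuracy(cm))
        f1ps.append(f1_pos)
        f1ms.append(f1_macro)
        recalls.append(cm.tp / cm.n_positive)
    return SubmodelStats(
        cv_accuracy=_mean_sd(cv_acc),
        cv_f1_macro=_mean_sd(cv_f1),
        test_balanced_accuracy=_mean_sd(bals),
        test_f1_pos=_mean_sd(f1ps),
        test_f1_macro=_mean_sd(f1ms),
        test_recall=_mean_sd(recalls),
        n_submodels=ensemble.n_submodels,
    )


@dataclass
class SweepResult:
    """One metrics report per voting threshold, from one set of vote fractions."""

    thresholds: list[float]
    reports: dict[float, MetricsReport]

    def metric_series(self, metric: str) -> list[float]:
        return [getattr(self.reports[p], metric) for p in self.thresholds]

    def fp_series(self) -> list[int]:
        return [self.reports[p].confusion.fp for p in self.thresholds]

    def to_long_rows(self) -> list[tuple[float, str, float]]:
        """Tidy (threshold, metric, value) rows for plotting."""
        rows = []
        for p in self.thresholds:
            r = self.reports[p]
            for metric in ("accuracy", "balanced_accuracy", "recall_pos", "f1_pos", "f1_macro"):
                rows.append((p, metric, getattr(r, metric)))
            rows.append((p, "false_positives", float(r.confusion.fp)))
        return rows

    def write_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("threshold,metric,value\n")
            for p, metric, value in self.to_long_rows():
                fh.write(f"{p},{metric},{value}\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "thresholds": self.thresholds,
                    "reports": {str(p): self.reports[p].to_dict() for p in self.thresholds},
                }
            ),
            encoding="utf-8",
        )


def sweep_thresholds(
    ensemble: EnsembleModel,
    test_features: FeatureMatrix,
    test_labels=None,
    ps: Sequence[float] = DEFAULT_THRESHOLDS,
) -> SweepResult:
    """Evaluate the ensemble at each voting threshold without refitting.

    Vote fractions are computed once; each threshold then reduces to a
    comparison, so the sweep is cheap and internally consistent.
    """
    for p in ps:
        if not 0.0 <= p < 1.0:
            raise ValueError(f"voting threshold p must be in [0, 1), got {p}")
    labels = test_features.labels if test_labels is None else np.asarray(test_labels, dtype=int)
    fractions = vote_fractions(ensemble, test_features)
    thresholds = sorted(ps)
    reports = {
        p: metrics_from_confusion(confusion(labels, (fractions > p).astype(int)))
        for p in thresholds
    }
    return SweepResult(thresholds=thresholds, reports=reports)
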