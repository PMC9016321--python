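"""Submodel training, threshold-voting ensembles, and single-model baselines.

The ensemble consists of ``n`` submodels, each fit on one balanced batch
(cross-validated for reporting, then refit on the full batch).  At
prediction time every submodel casts a binary vote and the ensemble
predicts positive only when the fraction of positive votes STRICTLY
exceeds the voting threshold ``p``: at ``p = 0.8`` with 20 submodels, 16
votes do not suffice and 17 do.  The threshold is a prediction-time
parameter — sweeping it never retrains anything.

The default submodel family is L2-regularized logistic regression with
unit regularization strength and a deterministic solver; linear / RBF /
degree-3 polynomial / sigmoid max-margin classifiers and random forests
are available as alternates for the single-classifier comparison grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.svm import SVC

from .batching import BalancedBatch
from .features import FeatureMatrix, Vocabulary
from .partition import FoldAssignment, make_cv_folds

__all__ = [
    "CLASSIFIER_KINDS",
    "TrainedSubmodel",
    "EnsembleModel",
    "make_classifier",
    "train_submodel",
    "train_ensemble",
    "vote_fractions",
    "ensemble_predict",
    "train_baseline_unbalanced",
    "train_baseline_undersampled",
]

CLASSIFIER_KINDS = (
    "logistic",
    "svm_linear",
    "svm_rbf",
    "svm_poly3",
    "svm_sigmoid",
    "random_forest",
)


def make_classifier(kind: str = "logistic", seed: int = 0):
    """Instantiate an untrained classifier of the given family."""
    if kind == "logistic":
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    if kind == "svm_linear":
        return SVC(kernel="linear", random_state=seed)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed)
    if kind == "svm_poly3":
        return SVC(kernel="poly", degree=3, random_state=seed)
    if kind == "svm_sigmoid":
        return SVC(kernel="sigmoid", random_state=seed)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}")


@dataclass
class TrainedSubmodel:
    """A fitted binary classifier plus its per-fold CV record."""

    estimator: object
    kind: str = "logistic"
    batch_name: str = ""
    cv_metrics: list[dict] = field(default_factory=list)
    feature_dim: int | None = None

    def predict(self, X) -> np.ndarray:
        if self.feature_dim is not None and X.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dimension mismatch: model expects {self.feature_dim}, got {X.shape[1]}"
            )
        return np.asarray(self.estimator.predict(X), dtype=int)

    @property
    def mean_cv_accuracy(self) -> float:
        if not self.cv_metrics:
            return float("nan")
        return float(np.mean([m["accuracy"] for m in self.cv_metrics]))

    @property
    def mean_cv_f1_macro(self) -> float:
        if not self.cv_metrics:
            return float("nan")
        return float(np.mean([m["f1_macro"] for m in self.cv_metrics]))


@dataclass
class EnsembleModel:
    """``n`` trained submodels + vocabulary + default voting threshold."""

    submodels: list[TrainedSubmodel]
    vocabulary: Vocabulary | None = None
    threshold: float = 0.8
    batching_mode: str = "random"

    def __post_init__(self) -> None:
        if not self.submodels:
            raise ValueError("an ensemble needs at least one submodel")
        dims = {m.feature_dim for m in self.submodels if m.feature_dim is not None}
        if len(dims) > 1:
            raise ValueError(f"submodels disagree on feature dimension: {sorted(dims)}")
        if not 0.0 <= self.threshold < 1.0:
            raise ValueError(f"threshold must be in [0, 1), got {self.threshold}")

    @property
    def n_submodels(self) -> int:
        return len(self.submodels)


def _as_matrix(features) -> sp.spmatrix:
    return features.X if isinstance(features, FeatureMatrix) else features


def train_submodel(
    batch: BalancedBatch,
    features: FeatureMatrix,
    folds: FoldAssignment | None = None,
    kind: str = "logistic",
    seed: int = 0,
    cv_folds: int = 10,
) -> TrainedSubmodel:
    """Fit one submodel on a balanced batch, with k-fold CV for reporting.

    Each CV fold trains on the remaining folds and records held-out
    accuracy and macro F1; the returned estimator is a refit on the full
    batch.  Deterministic given ``seed`` (which also seeds the fold
    assignment when ``folds`` is not supplied).
    """
    ids = batch.all_ids()
    try:
        sub = features.subset(ids)
    except KeyError as exc:
        raise ValueError(f"batch id {exc.args[0]!r} is missing from the feature matrix") from None
    if folds is None:
        folds = make_cv_folds(zip(ids, sub.labels.tolist()), k=cv_folds, seed=seed)
    missing = [sid for sid in ids if sid not in folds.fold_of]
    if missing:
        raise ValueError(f"fold assignment lacks {len(missing)} batch id(s), e.g. {missing[0]!r}")

    fold_idx = np.asarray([folds.fold_of[sid] for sid in ids])
    cv_metrics = []
    for f in range(folds.k):
        train_mask = fold_idx != f
        est = clone(make_classifier(kind, seed=seed))
        est.fit(sub.X[train_mask], sub.labels[train_mask])
        pred = est.predict(sub.X[~train_mask])
        truth = sub.labels[~train_mask]
        cv_metrics.append(
            {
                "fold": f,
                "accuracy": float(accuracy_score(truth, pred)),
                "f1_macro": float(f1_score(truth, pred, average="macro", zero_division=0)),
            }
        )
    final = clone(make_classifier(kind, seed=seed))
    final.fit(sub.X, sub.labels)
    return TrainedSubmodel(
        estimator=final,
        kind=kind,
        batch_name=batch.name,
        cv_metrics=cv_metrics,
        feature_dim=sub.n_features,
    )


def train_ensemble(
    batches: Sequence[BalancedBatch],
    features: FeatureMatrix,
    vocabulary: Vocabulary | None = None,
    kind: str = "logistic",
    threshold: float = 0.8,
    batching_mode: str = "random",
    seed: int = 0,
    cv_folds: int = 10,
) -> EnsembleModel:
    """Train one submodel per batch; per-submodel seeds derive from ``seed``."""
    submodels = [
        train_submodel(batch, features, kind=kind, seed=seed + i, cv_folds=cv_folds)
        for i, batch in enumerate(batches)
    ]
    return EnsembleModel(
        submodels=submodels,
        vocabulary=vocabulary,
        threshold=threshold,
        batching_mode=batching_mode,
    )


def vote_fractions(ensemble: EnsembleModel, features) -> np.ndarray:
    """Per-sample fraction of submodels voting positive, in {0, 1/n, ..., 1}."""
    X = _as_matrix(features)
    votes = np.zeros(X.shape[0], dtype=float)
    for sub in ensemble.submodels:
        votes += sub.predict(X)
    return votes / ensemble.n_submodels


def ensemble_predict(ensemble: EnsembleModel, features, p: float | None = None) -> np.ndarray:
    """Predict 1 iff the positive-vote fraction STRICTLY exceeds ``p``.

    ``p = 0`` reduces to a logical OR over submodels; with a single
    submodel and any ``p < 1`` below 1/1, the ensemble reproduces that
    submodel's predictions.
    """
    if p is None:
        p = ensemble.threshold
    if not 0.0 <= p < 1.0:
        raise ValueError(f"voting threshold p must be in [0, 1), got {p}")
    return (vote_fractions(ensemble, features) > p).astype(int)


def train_baseline_unbalanced(
    train_features: FeatureMatrix, kind: str = "logistic", seed: int = 0
) -> TrainedSubmodel:
    """Baseline 1: a single classifier fit on the full unbalanced training set."""
    labels = np.unique(train_features.labels)
    if len(labels) < 2:
        raise ValueError(f"training data contains a single class ({labels.tolist()})")
    est = make_classifier(kind, seed=seed)
    est.fit(train_features.X, train_features.labels)
    return TrainedSubmodel(
        estimator=est, kind=kind, batch_name="baseline1", feature_dim=train_features.n_features
    )


def train_baseline_undersampled(
    train_features: FeatureMatrix, seed: int = 0, kind: str = "logistic", cv_folds: int = 10
) -> TrainedSubmodel:
    """Baseline 2: one classifier on a single balanced undersampled batch.

    Equivalent by construction to a one-batch random ensemble with the
    same seed: the minority training ids are paired with an equal-size
    random majority draw and fit exactly as an ensemble submodel would be.
    """
    from .batching import make_random_batches

    minority = [sid for sid, lab in zip(train_features.sample_ids, train_features.labels) if lab == 1]
    majority = [sid for sid, lab in zip(train_features.sample_ids, train_features.labels) if lab == 0]
    (batch,) = make_random_batches(minority, majority, n_batches=1, seed=seed)
    return train_submodel(batch, train_features, kind=kind, seed=seed, cv_folds=cv_folds)


def ensemble_to_json(ensemble: EnsembleModel, path: str | Path) -> None:
    """Serialize a logistic ensemble (coefficients + intercepts + vocabulary)."""
    subs = []
    for m in ensemble.submodels:
        if m.kind != "logistic":
            raise ValueError("only logistic ensembles are JSON-serializable")
        est = m.estimator
        subs.append(
            {
                "batch_name": m.batch_name,
                "coef": np.asarray(est.coef_).ravel().tolist(),
                "intercept": float(np.asarray(est.intercept_).ravel()[0]),
                "classes": np.asarray(est.classes_).tolist(),
                "cv_metrics": m.cv_metrics,
            }
        )
    doc = {
        "n": ensemble.n_submodels,
        "threshold": ensemble.threshold,
        "batching_mode": ensemble.batching_mode,
        "vocabulary": None
        if ensemble.vocabulary is None
        else {"tokens": ensemble.vocabulary.tokens, "counts": ensemble.vocabulary.counts},
        "submodels": subs,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def ensemble_from_json(path: str | Path) -> EnsembleModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    submodels = []
    for sub in doc["submodels"]:
        est = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        est.classes_ = np.asarray(sub["classes"])
        est.coef_ = np.asarray([sub["coef"]])
        est.intercept_ = np.asarray([sub["intercept"]])
        est.n_features_in_ = len(sub["coef"])
        submodels.append(
            TrainedSubmodel(
                estimator=est,
                kind="logistic",
                batch_name=sub["batch_name"],
                cv_metrics=sub.get("cv_metrics", []),
                feature_dim=len(sub["coef"]),
            )
        )
    vocab = None
    if doc.get("vocabulary"):
        vocab = Vocabulary(
            tokens=list(doc["vocabulary"]["tokens"]), counts=list(doc["vocabulary"]["counts"])
        )
    return EnsembleModel(
        submodels=submodels,
        vocabulary=vocab,
        threshold=float(doc["threshold"]),
        batching_mode=doc["batching_mode"],
    )
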