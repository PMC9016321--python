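"""End-to-end experiment driver: filter -> split -> vectorize -> train -> evaluate.

This is the programmatic engine behind the command-line interface.  A
:class:`RunConfig` captures every knob of the protocol with defaults
matching the standard study settings (500-token vocabulary, 70/30
stratified split, 10-fold CV, 20 random batches, voting thresholds
0.4–0.9, 100-character length filter), and :func:`run_experiment`
executes one mode of the protocol on an in-memory corpus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import batching, corpus as corpus_mod, evaluation, features, models, partition
from .corpus import Corpus, DEFAULT_BURNOUT_KEYWORDS
from .evaluation import DEFAULT_THRESHOLDS

__all__ = ["RunConfig", "ExperimentResult", "run_experiment", "run_pipeline", "MODES"]

MODES = ("ensemble_random", "ensemble_group", "baseline1", "baseline2", "single_grid")


@dataclass
class RunConfig:
    """All protocol settings; defaults mirror the standard study setup."""

    vocab_size: int = 500
    test_fraction: float = 0.30
    cv_folds: int = 10
    n_batches: int = 20
    min_group_size: int | None = None  # None -> minority training count
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0
    min_chars: int = 100
    apply_length_filter: bool = True
    scrub_keywords: bool = False
    keywords: tuple[str, ...] = DEFAULT_BURNOUT_KEYWORDS
    classifier: str = "logistic"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data:
            data["thresholds"] = tuple(float(p) for p in data["thresholds"])
        if "keywords" in data:
            data["keywords"] = tuple(data["keywords"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    """Everything one experiment run produces, in memory."""

    mode: str
    config: RunConfig
    split: partition.SplitResult
    vocabulary: features.Vocabulary
    report: evaluation.MetricsReport | None = None
    sweep: evaluation.SweepResult | None = None
    submodel_stats: evaluation.SubmodelStats | None = None
    ensemble: models.EnsembleModel | None = None
    baseline: models.TrainedSubmodel | None = None
    grid_reports: dict[str, evaluation.MetricsReport] = field(default_factory=dict)
    grid_cv: dict[str, dict[str, float]] = field(default_factory=dict)
    batches: list[batching.BalancedBatch] = field(default_factory=list)


def prepare(corpus: Corpus, config: RunConfig) -> Corpus:
    """Apply the configured corpus filters (length filter, keyword scrub)."""
    out = corpus
    if config.apply_length_filter:
        out = corpus_mod.length_filter(out, config.min_chars)
    if config.scrub_keywords:
        out = corpus_mod.keyword_scrub(out, list(config.keywords))
    return out


def run_experiment(corpus: Corpus, config: RunConfig, mode: str) -> ExperimentResult:
    """Run one protocol mode end-to-end on a corpus.

    The corpus is filtered, split stratified 70/30, the vocabulary is fit
    on training documents only, and the mode's model(s) are trained on
    the training partition and evaluated on the held-out test partition.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    corpus = prepare(corpus, config)
    split = partition.stratified_split(corpus, config.test_fraction, seed=config.seed)
    train_corpus = corpus.subset(split.train_ids)
    test_corpus = corpus.subset(split.test_ids)
    vocab = features.build_vocabulary(train_corpus, size=config.vocab_size)
    train_X = features.vectorize(train_corpus, vocab)
    test_X = features.vectorize(test_corpus, vocab)
    result = ExperimentResult(mode=mode, config=config, split=split, vocabulary=vocab)

    minority = [s.id for s in train_corpus if s.label == 1]
    majority = [s.id for s in train_corpus if s.label == 0]

    if mode in ("ensemble_random", "ensemble_group"):
        if mode == "ensemble_random":
            result.batches = batching.make_random_batches(
                minority, majority, n_batches=config.n_batches, seed=config.seed
            )
        else:
            pairs = [(s.id, s.group) for s in train_corpus if s.label == 0]
            result.batches = batching.make_group_batches(
                minority, pairs, min_group_size=config.min_group_size, seed=config.seed
            )
        ensemble = models.train_ensemble(
            result.batches,
            train_X,
            vocabulary=vocab,
            kind=config.classifier,
            batching_mode="random" if mode == "ensemble_random" else "group",
            seed=config.seed,
            cv_folds=config.cv_folds,
        )
        result.ensemble = ensemble
        result.sweep = evaluation.sweep_thresholds(ensemble, test_X, ps=config.thresholds)
        result.report = evaluation.evaluate_model(ensemble, test_X, p=ensemble.threshold)
        result.submodel_stats = evaluation.submodel_statistics(ensemble, test_X)
    elif mode == "baseline1":
        result.baseline = models.train_baseline_unbalanced(
            train_X, kind=config.classifier, seed=config.seed
        )
        result.report = evaluation.evaluate_model(result.baseline, test_X)
    elif mode == "baseline2":
        result.baseline = models.train_baseline_undersampled(
            train_X, seed=config.seed, kind=config.classifier, cv_folds=config.cv_folds
        )
        result.report = evaluation.evaluate_model(result.baseline, test_X)
    else:  # single_grid
        folds = partition.make_cv_folds(
            zip(train_X.sample_ids, train_X.labels.tolist()), k=config.cv_folds, seed=config.seed
        )
        fold_idx = np.asarray([folds.fold_of[sid] for sid in train_X.sample_ids])
        for kind in models.CLASSIFIER_KINDS:
            accs, f1s = [], []
            for f in range(folds.k):
                mask = fold_idx != f
                est = models.make_classifier(kind, seed=config.seed)
                est.fit(train_X.X[mask], train_X.labels[mask])
                cm = evaluation.confusion(
                    train_X.labels[~mask], np.asarray(est.predict(train_X.X[~mask]), dtype=int)
                )
                accs.append(evaluation.accuracy(cm))
                f1s.append(evaluation.f1_scores(cm)[1])
            est = models.make_classifier(kind, seed=config.seed)
            est.fit(train_X.X, train_X.labels)
            sub = models.TrainedSubmodel(
                estimator=est, kind=kind, batch_name="grid", feature_dim=train_X.n_features
            )
            result.grid_reports[kind] = evaluation.evaluate_model(sub, test_X)
            result.grid_cv[kind] = {
                "mean_cv_accuracy": float(np.mean(accs)),
                "mean_cv_f1_macro": float(np.mean(f1s)),
            }
    return result


def run_pipeline(
    corpus: Corpus, config: RunConfig, mode: str, outdir: str | Path
) -> ExperimentResult:
    """Run an experiment and write all replayable artifacts to ``outdir``.

    Emits the resolved config (with hash and seed), the split, the
    vocabulary, batch id lists, the serialized model (logistic
    ensembles), metrics JSON, and the threshold sweep as JSON + tidy CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_experiment(corpus, config, mode)

    (outdir / "run_config.json").write_text(
        json.dumps(
            {"mode": mode, "config_hash": config.config_hash(), **dataclasses.asdict(config)},
            default=list,
        ),
        encoding="utf-8",
    )
    result.split.to_json(outdir / "split.json")
    result.vocabulary.to_json(outdir / "vocabulary.json")
    if result.batches:
        batching.batches_to_json(result.batches, outdir / "batches.json")
    if result.ensemble is not None and config.classifier == "logistic":
        models.ensemble_to_json(result.ensemble, outdir / "model.json")
    metrics: dict = {"mode": mode}
    if result.report is not None:
        metrics["report"] = result.report.to_dict()
    if result.submodel_stats is not None:
        metrics["submodel_stats"] = result.submodel_stats.to_dict()
    if result.grid_reports:
        metrics["grid"] = {
            kind: {**result.grid_reports[kind].to_dict(), **result.grid_cv[kind]}
            for kind in result.grid_reports
        }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2), encoding="utf-8")
    if result.sweep is not None:
        result.sweep.to_json(outdir / "sweep.json")
        result.sweep.write_csv(outdir / "sweep.csv")
    return result
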