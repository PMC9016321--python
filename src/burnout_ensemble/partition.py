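"""Stratified train/test splitting and cross-validation fold assignment.

Both operations are functions of (ids, labels, seed) only — never of text
content — so a split can be replayed exactly from its serialized form.

The per-class test count is ``round-half-up(test_fraction * n_c)``.  With
a 70/30 split of a 13,216-control / 352-positive corpus this yields a
test set of 4,071 samples (106 positive) and 246 positive training
samples, the counts around which balanced ensemble batches of 492 are
built.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Corpus

__all__ = ["SplitResult", "FoldAssignment", "stratified_split", "make_cv_folds"]


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


@dataclass
class SplitResult:
    """A stratified train/test partition of corpus ids."""

    train_ids: list[str]
    test_ids: list[str]
    test_fraction: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "train_ids": self.train_ids,
                    "test_ids": self.test_ids,
                    "test_fraction": self.test_fraction,
                    "seed": self.seed,
                }
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            train_ids=list(d["train_ids"]),
            test_ids=list(d["test_ids"]),
            test_fraction=float(d["test_fraction"]),
            seed=int(d["seed"]),
        )


@dataclass
class FoldAssignment:
    """A stratified k-fold assignment: id -> fold index in 0..k-1."""

    fold_of: dict[str, int]
    k: int

    def fold_ids(self, fold: int) -> list[str]:
        return [sid for sid, f in self.fold_of.items() if f == fold]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"k": self.k, "fold_of": self.fold_of}), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FoldAssignment":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(fold_of={str(k): int(v) for k, v in d["fold_of"].items()}, k=int(d["k"]))


def stratified_split(corpus: Corpus, test_fraction: float = 0.30, seed: int = 0) -> SplitResult:
    """Split a corpus into stratified train/test id lists.

    For each class with ``n_c`` samples, exactly
    ``round-half-up(test_fraction * n_c)`` samples go to the test set;
    membership is random under ``seed`` and deterministic given it.

    Raises
    ------
    ValueError
        If ``test_fraction`` is outside (0, 1) or any class has fewer
        than 2 samples.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for s in corpus:
        by_class.setdefault(s.label, []).append(s.id)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for label in sorted(by_class):
        ids = by_class[label]
        if len(ids) < 2:
            raise ValueError(f"class {label} has {len(ids)} sample(s); need at least 2 to split")
        n_test = _round_half_up(test_fraction * len(ids))
        perm = rng.permutation(len(ids))
        test_ids.extend(ids[i] for i in perm[:n_test])
        train_ids.extend(ids[i] for i in perm[n_test:])
    return SplitResult(
        train_ids=train_ids, test_ids=test_ids, test_fraction=test_fraction, seed=seed
    )


def make_cv_folds(
    ids_with_labels: Iterable[tuple[str, int]], k: int = 10, seed: int = 0
) -> FoldAssignment:
    """Assign ids to k stratified cross-validation folds.

    Within each class, fold sizes differ by at most one; the classes'
    surplus samples are staggered across folds so overall fold sizes also
    differ by at most one.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If ``k < 2`` or any class has fewer than ``k`` samples.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    pairs = list(ids_with_labels)
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for sid, label in pairs:
        by_class.setdefault(label, []).append(sid)
    fold_of: dict[str, int] = {}
    start = 0  # rotating offset staggering each class's surplus folds
    for label in sorted(by_class):
        ids = by_class[label]
        if len(ids) < k:
            raise ValueError(f"class {label} has {len(ids)} sample(s); need at least k={k}")
        perm = rng.permutation(len(ids))
        for i, p in enumerate(perm):
            fold_of[ids[p]] = (start + i) % k
        start = (start + len(ids)) % k
    return FoldAssignment(fold_of=fold_of, k=k)
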