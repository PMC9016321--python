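"""Bag-of-words front-end: tokenizer, vocabulary, count vectorization.

Documents are represented as vectors of raw token counts over a fixed
vocabulary of the most frequent tokens (default 500) in a reference
corpus — usually the training split only, to avoid test-set leakage.

The built-in tokenizer is deliberately minimal and fully deterministic:
lowercase, alphabetic tokens only, punctuation and digits act as
separators, no stop-word removal and no lemmatization.  Any callable with
the same ``str -> list[str]`` signature can be passed in its place to
plug an external NLP pipeline.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from .corpus import Corpus

__all__ = ["tokenize", "Vocabulary", "FeatureMatrix", "build_vocabulary", "vectorize"]

Tokenizer = Callable[[str], list[str]]

# Unicode letters only; digits, underscores and punctuation separate tokens.
_TOKEN_RE = re.compile(r"[^\W\d_]+")


def tokenize(text: str) -> list[str]:
    """Split text into lowercase alphabetic tokens.

    ``"Burnt-out, again!"`` becomes ``["burnt", "out", "again"]``.  The
    function is idempotent on its own space-joined output and returns an
    empty list for empty text.
    """
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Vocabulary:
    """An ordered list of distinct tokens with their corpus frequencies.

    Tokens are ordered by total count (descending), ties broken
    lexicographically ascending, and truncated to the configured size.
    """

    tokens: list[str]
    counts: list[int]
    source: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(set(self.tokens)):
            raise ValueError("vocabulary tokens must be distinct")
        if len(self.counts) != len(self.tokens):
            raise ValueError("tokens and counts must align")
        if any(b > a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("vocabulary counts must be non-increasing")
        self._index = {t: j for j, t in enumerate(self.tokens)}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index_of(self, token: str) -> int:
        return self._index[token]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"size": len(self.tokens), "tokens": self.tokens, "counts": self.counts},
                ensure_ascii=False,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(tokens=list(data["tokens"]), counts=list(data["counts"]))


@dataclass
class FeatureMatrix:
    """Sparse token-count matrix with aligned sample ids and labels."""

    X: sp.csr_matrix
    sample_ids: list[str]
    labels: np.ndarray
    _row: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != len(self.sample_ids) or len(self.sample_ids) != len(self.labels):
            raise ValueError("rows, sample_ids and labels must align")
        self._row = {sid: i for i, sid in enumerate(self.sample_ids)}

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        rows = [self._row[sid] for sid in sample_ids]
        return FeatureMatrix(
            X=self.X[rows], sample_ids=list(sample_ids), labels=self.labels[rows]
        )

    def rows_for(self, sample_ids: Sequence[str]) -> sp.csr_matrix:
        return self.X[[self._row[sid] for sid in sample_ids]]

    def write_csv(self, path: str | Path) -> None:
        """Dense CSV export: header ``id,label,t1..tK``."""
        dense = self.X.toarray()
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("id,label," + ",".join(f"t{j+1}" for j in range(self.n_features)) + "\n")
            for sid, lab, row in zip(self.sample_ids, self.labels, dense):
                fh.write(f"{sid},{lab}," + ",".join(str(int(v)) for v in row) + "\n")

    def write_triplets(self, path: str | Path) -> None:
        """Sparse triplet export: ``row,col,count`` lines (0-based)."""
        coo = self.X.tocoo()
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("row,col,count\n")
            for r, c, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{r},{c},{int(v)}\n")


def build_vocabulary(
    corpus: Corpus,
    size: int = 500,
    tokenizer: Tokenizer = tokenize,
) -> Vocabulary:
    """Collect the ``size`` most frequent tokens across a corpus.

    Frequency is the total token count over all documents (not document
    frequency).  Ties are broken lexicographically ascending so the
    result is deterministic and invariant to document order.  If fewer
    distinct tokens exist, the vocabulary is simply shorter.

    Raises
    ------
    ValueError
        If ``size < 1`` or the corpus yields no tokens at all.
    """
    if size < 1:
        raise ValueError(f"vocabulary size must be positive, got {size}")
    totals: Counter[str] = Counter()
    for s in corpus:
        totals.update(tokenizer(s.text))
    if not totals:
        raise ValueError("corpus contains no tokens; cannot build a vocabulary")
    ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))[:size]
    return Vocabulary(
        tokens=[t for t, _ in ranked],
        counts=[c for _, c in ranked],
        source=corpus.provenance,
    )


def vectorize(
    corpus: Corpus,
    vocab: Vocabulary,
    tokenizer: Tokenizer = tokenize,
) -> FeatureMatrix:
    """Count vocabulary-token occurrences per document.

    Entry ``(i, j)`` is the number of times vocabulary token ``j`` occurs
    in document ``i``; out-of-vocabulary tokens are ignored.  Empty
    documents yield zero rows.
    """
    if len(vocab) == 0:
        raise ValueError("vocabulary must be non-empty")
    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for s in corpus:
        doc_counts = Counter(
            vocab.index_of(t) for t in tokenizer(s.text) if t in vocab
        )
        indices.extend(doc_counts.keys())
        data.extend(doc_counts.values())
        indptr.append(len(indices))
    X = sp.csr_matrix(
        (np.asarray(data, dtype=np.int64), np.asarray(indices, dtype=np.int32), indptr),
        shape=(len(corpus), len(vocab)),
    )
    X.sort_indices()
    return FeatureMatrix(X=X, sample_ids=corpus.ids(), labels=np.asarray(corpus.labels()))
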