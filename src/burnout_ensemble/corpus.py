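"""Labeled text corpora: data model, JSONL/CSV I/O, and corpus filters.

A corpus is an ordered collection of labeled documents.  The positive class
(label 1) marks documents describing the condition of interest (burnout
first-person accounts); the control class (label 0) is everything else
(general posts or depression accounts, depending on the experiment).  An
optional free-form ``group`` tag records the topical community a control
document came from and drives group-based ensemble batching.

Three corpus-level filters are provided:

* :func:`length_filter` — drop documents shorter than a character minimum
  (used to remove near-empty posts before any modeling).
* :func:`keyword_scrub` — remove every occurrence of a set of search
  phrases from every document (used to test whether classifiers merely
  detect the phrases the corpus was collected with).
* :func:`make_balanced_pair` — build a 50/50 dataset from a positive
  corpus plus an equal-size random undersample of a control corpus.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "TextSample",
    "Corpus",
    "CorpusParseError",
    "InsufficientDataError",
    "DEFAULT_BURNOUT_KEYWORDS",
    "read_corpus",
    "write_corpus",
    "length_filter",
    "keyword_scrub",
    "make_balanced_pair",
]

#: Search-phrase variants used to collect burnout posts.  Scrubbing these
#: from positive documents tests whether a classifier relies on the
#: collection keywords themselves rather than on content.
DEFAULT_BURNOUT_KEYWORDS: tuple[str, ...] = (
    "burnout",
    "burn out",
    "burned out",
    "burning out",
    "burnt out",
    "burn-out",
    "burnedout",
    "burntout",
)


class CorpusParseError(ValueError):
    """A corpus file contained a malformed or invalid record."""


class InsufficientDataError(ValueError):
    """An operation needed more samples than the corpus provides."""


@dataclass(frozen=True)
class TextSample:
    """One labeled document.

    Parameters
    ----------
    id : str
        Unique identifier within its corpus.
    text : str
        Raw document text (free text, arbitrary length).
    label : int
        Binary class: 1 = positive (burnout), 0 = control.
    group : str or None
        Optional topical-community tag (e.g. the subreddit a control
        post came from).  ``None`` means untagged.
    """

    id: str
    text: str
    label: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass
class Corpus:
    """An ordered collection of :class:`TextSample` with unique ids."""

    samples: list[TextSample]
    provenance: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {}
        for i, s in enumerate(self.samples):
            if s.id in self._index:
                raise CorpusParseError(f"duplicate sample id {s.id!r}")
            self._index[s.id] = i

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[TextSample]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> TextSample:
        return self.samples[self._index[sample_id]]

    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def labels(self) -> list[int]:
        return [s.label for s in self.samples]

    def texts(self) -> list[str]:
        return [s.text for s in self.samples]

    def class_counts(self) -> dict[int, int]:
        counts = {0: 0, 1: 0}
        for s in self.samples:
            counts[s.label] += 1
        return counts

    def subset(self, sample_ids: Sequence[str], provenance: str | None = None) -> "Corpus":
        """Return a new corpus with the given ids, in the given order."""
        samples = [self.samples[self._index[i]] for i in sample_ids]
        return Corpus(samples, provenance or self.provenance)

    def filter(self, predicate, provenance: str | None = None) -> "Corpus":
        return Corpus([s for s in self.samples if predicate(s)], provenance or self.provenance)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("jsonl", "csv"):
            raise ValueError(f"unknown corpus format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "jsonl"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer corpus format from {path.name!r}; pass format=")


def _sample_from_record(record: dict, where: str) -> TextSample:
    try:
        sid = record["id"]
        text = record["text"]
        label = record["label"]
    except KeyError as exc:
        raise CorpusParseError(f"{where}: missing field {exc.args[0]!r}") from None
    group = record.get("group")
    if group == "" or group is None:
        group = None
    try:
        label = int(label)
    except (TypeError, ValueError):
        raise CorpusParseError(f"{where}: label {label!r} is not an integer") from None
    if label not in (0, 1):
        raise CorpusParseError(f"{where}: label must be 0 or 1, got {label}")
    return TextSample(id=str(sid), text=str(text), label=label, group=group)


def read_corpus(path: str | Path, format: str | None = None) -> Corpus:
    """Read a labeled corpus from JSONL (canonical) or CSV.

    JSONL records look like ``{"id": ..., "text": ..., "label": 0|1,
    "group": ...|null}``; CSV uses a header ``id,text,label,group`` with
    RFC-4180 quoting.  Record order is preserved.  A missing or empty
    group is stored as absent (``None``), never as an empty string.

    Raises
    ------
    CorpusParseError
        On a malformed record (the message names the offending
        line/record) or a duplicate id.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    samples: list[TextSample] = []
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusParseError(f"line {lineno}: invalid JSON ({exc.msg})") from None
                samples.append(_sample_from_record(record, f"line {lineno}"))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for recno, row in enumerate(reader, start=1):
                samples.append(_sample_from_record(row, f"record {recno}"))
    return Corpus(samples, provenance=str(path))


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus to JSONL or CSV, preserving sample order."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for s in corpus:
                fh.write(
                    json.dumps(
                        {"id": s.id, "text": s.text, "label": s.label, "group": s.group},
                        ensure_ascii=False,
                    )
                )
                fh.write("\n")
    else:
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "text", "label", "group"])
            for s in corpus:
                writer.writerow([s.id, s.text, s.label, "" if s.group is None else s.group])


def corpus_to_jsonl_bytes(corpus: Corpus) -> bytes:
    """Serialize a corpus to canonical JSONL bytes (for checksums/tests)."""
    buf = io.StringIO()
    for s in corpus:
        buf.write(
            json.dumps(
                {"id": s.id, "text": s.text, "label": s.label, "group": s.group},
                ensure_ascii=False,
            )
        )
        buf.write("\n")
    return buf.getvalue().encode("utf-8")


def length_filter(corpus: Corpus, min_chars: int) -> Corpus:
    """Keep documents whose raw character count is at least ``min_chars``.

    The count is over raw Unicode characters of the original text, before
    any tokenization.  Documents with fewer characters are dropped; order
    is preserved and an empty result is legal.
    """
    if min_chars < 1:
        raise ValueError(f"min_chars must be >= 1, got {min_chars}")
    return corpus.filter(lambda s: len(s.text) >= min_chars)


def _keyword_pattern(keywords: Sequence[str]) -> re.Pattern:
    # Longest phrase first so "burnt out" is removed before "burnt" could
    # ever match a sub-phrase; word-boundary anchored, case-insensitive.
    ordered = sorted(set(keywords), key=lambda k: (-len(k), k))
    alternation = "|".join(re.escape(k) for k in ordered)
    return re.compile(rf"\b(?:{alternation})\b", re.IGNORECASE)


def keyword_scrub(corpus: Corpus, keywords: Sequence[str] = DEFAULT_BURNOUT_KEYWORDS) -> Corpus:
    """Remove every occurrence of every keyword phrase from every text.

    Matching is case-insensitive, word-boundary anchored, and
    longest-phrase-first.  Runs of spaces left behind by a removal are
    collapsed to a single space.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    pattern = _keyword_pattern(keywords)
    out = []
    for s in corpus:
        text = pattern.sub("", s.text)
        text = re.sub(r"  +", " ", text)
        out.append(TextSample(id=s.id, text=text, label=s.label, group=s.group))
    return Corpus(out, provenance=corpus.provenance)


def make_balanced_pair(positives: Corpus, controls: Corpus, seed: int) -> Corpus:
    """Pair all positives with an equal-size random control undersample.

    Controls are sampled without replacement under ``seed``; the result
    has exactly equal class counts (all positives first, then the sampled
    controls) and size ``2 * len(positives)``.

    Raises
    ------
    InsufficientDataError
        If the control corpus is smaller than the positive corpus.
    """
    n = len(positives)
    if len(controls) < n:
        raise InsufficientDataError(
            f"need at least {n} control samples to balance {n} positives, "
            f"have {len(controls)}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(controls), size=n, replace=False)
    samples = list(positives.samples) + [controls.samples[i] for i in chosen]
    return Corpus(samples, provenance="balanced pair")
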