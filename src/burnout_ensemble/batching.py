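"""Balanced training batches for undersampling ensembles.

Every batch pairs the full minority-class training set with an
equal-size, disjoint draw from the majority class, in the style of
UnderBagging.  Two constructions are provided: ``make_random_batches``
slices a random permutation of the majority ids into disjoint chunks;
``make_group_batches`` builds one batch per sufficiently large topical
group (e.g. subreddit), sampling within the group only.  Leftover
majority samples are simply unused — the majority class is never
exhausted by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import InsufficientDataError

__all__ = ["BalancedBatch", "make_random_batches", "make_group_batches"]


@dataclass
class BalancedBatch:
    """A 50/50 training batch: shared minority ids + batch-specific majority ids."""

    minority_ids: list[str]
    majority_ids: list[str]
    name: str

    def __post_init__(self) -> None:
        if len(self.minority_ids) != len(self.majority_ids):
            raise ValueError(
                f"batch {self.name!r}: minority ({len(self.minority_ids)}) and majority "
                f"({len(self.majority_ids)}) id lists must have equal length"
            )
        if set(self.minority_ids) & set(self.majority_ids):
            raise ValueError(f"batch {self.name!r}: minority and majority ids overlap")

    @property
    def size(self) -> int:
        return 2 * len(self.minority_ids)

    def all_ids(self) -> list[str]:
        return list(self.minority_ids) + list(self.majority_ids)


def make_random_batches(
    train_minority_ids: Sequence[str],
    train_majority_ids: Sequence[str],
    n_batches: int,
    seed: int,
) -> list[BalancedBatch]:
    """Build ``n_batches`` balanced batches with disjoint majority draws.

    All batches share the full minority id list; the majority ids are a
    random permutation (under ``seed``) sliced into consecutive chunks,
    so the majority sets are pairwise disjoint and each batch's content
    depends only on (seed, batch index).

    Raises
    ------
    InsufficientDataError
        If the majority pool cannot supply ``n_batches`` disjoint chunks;
        the message reports the maximum feasible batch count.
    """
    if n_batches < 1:
        raise ValueError(f"n_batches must be >= 1, got {n_batches}")
    m = len(train_minority_ids)
    if m == 0:
        raise ValueError("minority id list is empty")
    needed = n_batches * m
    if len(train_majority_ids) < needed:
        feasible = len(train_majority_ids) // m
        raise InsufficientDataError(
            f"{len(train_majority_ids)} majority samples cannot fill {n_batches} disjoint "
            f"batches of {m}; at most {feasible} batch(es) feasible"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(train_majority_ids))
    minority = list(train_minority_ids)
    batches = []
    for i in range(n_batches):
        chunk = [train_majority_ids[j] for j in perm[i * m : (i + 1) * m]]
        batches.append(BalancedBatch(minority_ids=minority, majority_ids=chunk, name=f"random-{i:02d}"))
    return batches


def make_group_batches(
    train_minority_ids: Sequence[str],
    train_majority_samples_with_groups: Sequence[tuple[str, str | None]],
    min_group_size: int | None = None,
    seed: int = 0,
) -> list[BalancedBatch]:
    """Build one balanced batch per sufficiently large majority group.

    ``train_majority_samples_with_groups`` is a sequence of
    ``(id, group)`` pairs for the majority training samples.  Every group
    whose training count is at least ``min_group_size`` (default: the
    minority count, so a full balanced batch can be drawn) yields one
    batch whose majority ids are sampled without replacement from within
    that single group, using a per-batch seed ``seed + batch_index`` over
    groups in sorted-name order.  Batches are named after their group.

    Raises
    ------
    InsufficientDataError
        If no group qualifies; the message lists the observed group sizes.
    """
    m = len(train_minority_ids)
    if m == 0:
        raise ValueError("minority id list is empty")
    if min_group_size is None:
        min_group_size = m
    if min_group_size < m:
        raise ValueError(
            f"min_group_size ({min_group_size}) must be at least the minority count ({m}) "
            "to draw a balanced batch without replacement"
        )
    groups: dict[str, list[str]] = {}
    for sid, group in train_majority_samples_with_groups:
        if group is None:
            continue
        groups.setdefault(group, []).append(sid)
    qualifying = sorted(g for g, ids in groups.items() if len(ids) >= min_group_size)
    if not qualifying:
        sizes = {g: len(ids) for g, ids in sorted(groups.items())}
        raise InsufficientDataError(
            f"no group has >= {min_group_size} training majority samples; sizes: {sizes}"
        )
    minority = list(train_minority_ids)
    batches = []
    for i, group in enumerate(qualifying):
        pool = groups[group]
        rng = np.random.default_rng(seed + i)
        chosen = rng.choice(len(pool), size=m, replace=False)
        batches.append(
            BalancedBatch(
                minority_ids=minority,
                majority_ids=[pool[j] for j in chosen],
                name=group,
            )
        )
    return batches


def batches_to_json(batches: Sequence[BalancedBatch], path: str | Path) -> None:
    """Serialize batches as replayable id lists."""
    Path(path).write_text(
        json.dumps(
            [
                {"name": b.name, "minority_ids": b.minority_ids, "majority_ids": b.majority_ids}
                for b in batches
            ]
        ),
        encoding="utf-8",
    )


def batches_from_json(path: str | Path) -> list[BalancedBatch]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        BalancedBatch(
            minority_ids=list(d["minority_ids"]),
            majority_ids=list(d["majority_ids"]),
            name=d["name"],
        )
        for d in data
    ]
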