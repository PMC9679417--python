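"""Chronological splitting for prospective (time-split) validation.

Drugs approved before a cutoff year form the locked development pool; drugs
approved at or after the cutoff form the test pool, which is partitioned
into chronological buckets by inclusive approval-year ranges.  The default
configuration follows the DILIst audit design: cutoff 1997 and five buckets
1997-1998, 1999-2001, 2002-2004, 2005-2007, 2008-2019.

For a chosen test bucket, the adaptive schedule lists the cumulative
chronological prefixes of the *remaining* buckets; each prefix, appended to
the locked pool, trains one retrained ("adaptive") model.  With B buckets
this yields B-1 stages per test bucket — at most four buckets of new drugs
are ever added when B = 5.  Note that for an interior test bucket the later
buckets are still added in chronological order, so an adaptive model may
train on drugs approved after its test period; this mirrors the audited
protocol and is intentional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roster import Roster

__all__ = [
    "BucketSpec",
    "SplitPlan",
    "AdaptiveSchedule",
    "DEFAULT_CUTOFF_YEAR",
    "DEFAULT_BUCKET_SPEC",
    "split_by_cutoff",
    "assign_buckets",
    "build_adaptive_schedule",
    "make_split_plan",
]

DEFAULT_CUTOFF_YEAR = 1997


@dataclass(frozen=True)
class BucketSpec:
    """Ordered, non-overlapping inclusive year ranges partitioning the test pool."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ranges = tuple((int(a), int(b)) for a, b in self.ranges)
        object.__setattr__(self, "ranges", ranges)
        for start, end in ranges:
            if end < start:
                raise ValueError(f"range ({start}, {end}) has end < start")
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"ranges ({s1},{e1}) and ({s2},{e2}) overlap or are unsorted"
                )

    def __len__(self) -> int:
        return len(self.ranges)

    def index_of(self, year: int) -> int | None:
        """0-based index of the range covering ``year``, or None if uncovered."""
        for i, (start, end) in enumerate(self.ranges):
            if start <= year <= end:
                return i
        return None

    def label(self, i: int) -> str:
        start, end = self.ranges[i]
        return f"{start}-{end}"

    @classmethod
    def parse(cls, text: str) -> "BucketSpec":
        """Parse ``"1997-1998,1999-2001,..."`` into a BucketSpec."""
        ranges = []
        for part in text.split(","):
            start, _, end = part.strip().partition("-")
            ranges.append((int(start), int(end or start)))
        return cls(ranges=tuple(ranges))


DEFAULT_BUCKET_SPEC = BucketSpec(
    ranges=((1997, 1998), (1999, 2001), (2002, 2004), (2005, 2007), (2008, 2019))
)


@dataclass(frozen=True)
class SplitPlan:
    """Locked pool, test pool, and the bucketed partition of the test pool."""

    locked_pool: Roster
    test_pool: Roster
    buckets: tuple[Roster, ...]
    bucket_spec: BucketSpec
    cutoff_year: int

    @property
    def n_buckets(self) -> int:
        return len(self.buckets)


@dataclass(frozen=True)
class AdaptiveSchedule:
    """Cumulative training stages for one test bucket.

    ``stages[k]`` is the tuple of 1-based bucket indices (sorted ascending,
    i.e. chronological) whose drugs augment the locked pool at stage k+1.
    Stages are strictly nested prefixes and never contain the test bucket.
    """

    test_bucket_index: int
    stages: tuple[tuple[int, ...], ...]


def split_by_cutoff(roster: Roster, cutoff_year: int = DEFAULT_CUTOFF_YEAR):
    """Split a roster at an approval-year cutoff.

    A record goes to the locked pool iff ``approval_year < cutoff_year``
    (strict), otherwise to the test pool; row order is preserved within
    each pool.

    Returns
    -------
    (locked_pool, test_pool) : tuple of Roster
    """
    if len(roster) == 0:
        raise ValueError("roster is empty")
    locked_mask = roster.approval_years < cutoff_year
    return roster.subset(locked_mask), roster.subset(~locked_mask)


def assign_buckets(test_pool: Roster, spec: BucketSpec = DEFAULT_BUCKET_SPEC):
    """Partition the test pool into chronological buckets.

    Every approval year in the test pool must be covered by exactly one
    range of ``spec``; an uncovered year raises a ValueError naming the
    year and the offending record.

    Returns
    -------
    tuple of Roster, one per range, in range order.
    """
    assignments = np.empty(len(test_pool), dtype=int)
    for row, year in enumerate(test_pool.approval_years):
        idx = spec.index_of(int(year))
        if idx is None:
            raise ValueError(
                f"approval year {year} (drug {test_pool.drug_ids[row]}) "
                f"is not covered by any bucket range"
            )
        assignments[row] = idx
    return tuple(test_pool.subset(assignments == i) for i in range(len(spec)))


def build_adaptive_schedule(n_buckets: int, test_bucket_index: int) -> AdaptiveSchedule:
    """Cumulative chronological training schedule for one test bucket.

    The remaining buckets (all except the test bucket) are sorted ascending
    and stage k is their first k elements, k = 1 .. n_buckets - 1.

    Parameters
    ----------
    n_buckets : int
        Total number of buckets B (>= 2).
    test_bucket_index : int
        1-based index of the held-out test bucket.
    """
    if n_buckets < 2:
        raise ValueError("need at least two buckets")
    if not 1 <= test_bucket_index <= n_buckets:
        raise ValueError(
            f"test_bucket_index {test_bucket_index} out of range 1..{n_buckets}"
        )
    remaining = [i for i in range(1, n_buckets + 1) if i != test_bucket_index]
    stages = tuple(tuple(remaining[:k]) for k in range(1, n_buckets))
    return AdaptiveSchedule(test_bucket_index=test_bucket_index, stages=stages)


def make_split_plan(
    roster: Roster,
    cutoff_year: int = DEFAULT_CUTOFF_YEAR,
    spec: BucketSpec = DEFAULT_BUCKET_SPEC,
) -> SplitPlan:
    """Cutoff split plus bucket assignment in one step."""
    locked, test = split_by_cutoff(roster, cutoff_year)
    buckets = assign_buckets(test, spec)
    return SplitPlan(
        locked_pool=locked,
        test_pool=test,
        buckets=buckets,
        bucket_spec=spec,
        cutoff_year=cutoff_year,
    )
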