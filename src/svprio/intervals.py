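"""Interval algebra: reciprocal overlap and chromosome-partitioned indexes.

Reciprocal overlap is the standard SV-identity measure: the overlap length
divided by each interval's own length, taking the minimum. Two calls "are
the same SV" when that fraction reaches a threshold (0.5 by default here).
"""

from __future__ import annotations

from typing import Generic, Sequence, TypeVar

from intervaltree import IntervalTree

from .model import GenomicInterval

T = TypeVar("T")


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(ov/len(a), ov/len(b)); 0 for different chromosomes or zero-length."""
    if a.chrom != b.chrom:
        return 0.0
    la, lb = a.length(), b.length()
    if la == 0 or lb == 0:
        return 0.0
    ov = a.overlap_length(b)
    return min(ov / la, ov / lb)


class FeatureIndex(Generic[T]):
    """Chromosome-keyed interval-tree index over arbitrary features.

    Query results are deterministic: sorted by (start, feature id).
    """

    def __init__(self, features: Sequence[tuple[GenomicInterval, str, T]]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for interval, fid, payload in features:
            tree = self._trees.setdefault(interval.chrom, IntervalTree())
            # intervaltree rejects null intervals; pad points by one for indexing,
            # real overlap is re-checked against the stored interval below.
            end = interval.end if interval.end > interval.start else interval.start + 1
            tree[interval.start:end] = (interval, fid, payload)

    def query(self, interval: GenomicInterval) -> list[tuple[GenomicInterval, str, T]]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        if interval.start == interval.end:
            raw = tree[interval.start]
        else:
            raw = tree[interval.start:interval.end]
        hits = [iv.data for iv in raw if interval.overlaps(iv.data[0])]
        hits.sort(key=lambda h: (h[0].start, h[1]))
        return hits


def overlap_scan(
    features: Sequence[tuple[GenomicInterval, str, T]], interval: GenomicInterval
) -> list[tuple[GenomicInterval, str, T]]:
    """Brute-force linear scan with the same contract as FeatureIndex.query."""
    hits = [f for f in features if interval.overlaps(f[0])]
    hits.sort(key=lambda h: (h[0].start, h[1]))
    return hits


def format_ranges(numbers: Sequence[int]) -> str:
    """Collapse sorted integers into maximal consecutive ranges: "58-61, 64-66"."""
    if not numbers:
        return ""
    nums = sorted(set(numbers))
    runs: list[tuple[int, int]] = []
    lo = hi = nums[0]
    for n in nums[1:]:
        if n == hi + 1:
            hi = n
        else:
            runs.append((lo, hi))
            lo = hi = n
    runs.append((lo, hi))
    return ", ".join(f"{a}" if a == b else f"{a}-{b}" for a, b in runs)
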