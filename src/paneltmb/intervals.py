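"""Genomic interval primitives: validation, merging and fast overlap queries.

All coordinates are 0-based, half-open (BED convention). GTF input is converted
on read; VCF positions are converted at the point of use.
"""
from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: negative start"
            )
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: end must exceed start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping *and touching* intervals into a sorted, disjoint list.

    Touching intervals are merged so that footprint sizes count every base
    exactly once. The union of base positions is preserved.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of distinct bases covered (intervals are merged first)."""
    return sum(iv.length for iv in merge_intervals(intervals))


def length_mb(intervals: Iterable[GenomicInterval]) -> float:
    return total_length(intervals) / 1e6


class FootprintIndex:
    """Binary-search index over a merged footprint for O(log n) overlap queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        merged = merge_intervals(intervals)
        self.intervals: tuple[GenomicInterval, ...] = tuple(merged)
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, group in groupby(merged, key=lambda iv: iv.chrom):
            ivs = list(group)
            self._by_chrom[chrom] = ([iv.start for iv in ivs], [iv.end for iv in ivs])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) shares at least one base with the footprint."""
        if end <= start:
            raise ValueError(f"empty query span {chrom}:{start}-{end}")
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        # Candidate: the last footprint interval starting before the query end.
        i = bisect_left(starts, end) - 1
        return i >= 0 and ends[i] > start

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


def covered_positions(intervals: Sequence[GenomicInterval]) -> set[tuple[str, int]]:
    """Explicit per-base representation; intended for small inputs and oracle checks."""
    pos: set[tuple[str, int]] = set()
    for iv in intervals:
        for p in range(iv.start, iv.end):
            pos.add((iv.chrom, p))
    return pos
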