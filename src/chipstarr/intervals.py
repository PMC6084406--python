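"""Genomic interval primitives.

All coordinates in this package are 0-based, half-open (BED convention).
Dialects that use 1-based inclusive coordinates are converted at the I/O
boundary, never inside the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unknown). Width must be positive.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap test; book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], book_ended: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping intervals into a strand-blind, sorted, disjoint set.

    With ``book_ended=True`` (default) abutting intervals (end == start) are
    also merged, matching the default behaviour of common merge tools.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom:
            prev = merged[-1]
            gap = iv.start - prev.end
            if gap < 0 or (book_ended and gap == 0):
                if iv.end > prev.end:
                    merged[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
                continue
        merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.width for iv in merge_intervals(intervals, book_ended=True))


def overlap_join(
    q_chrom: Sequence[str],
    q_start: np.ndarray,
    q_end: np.ndarray,
    s_chrom: Sequence[str],
    s_start: np.ndarray,
    s_end: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs half-open overlap join between two interval sets.

    Returns two aligned index arrays (query_idx, subject_idx), one row per
    overlapping pair. Subjects are indexed per chromosome with sorted starts
    plus a running maximum of ends, so the scan window for each query is
    [first index whose running max end exceeds q_start, first start >= q_end).
    """
    q_start = np.asarray(q_start, dtype=np.int64)
    q_end = np.asarray(q_end, dtype=np.int64)
    s_start = np.asarray(s_start, dtype=np.int64)
    s_end = np.asarray(s_end, dtype=np.int64)
    q_chrom = np.asarray(q_chrom, dtype=object)
    s_chrom = np.asarray(s_chrom, dtype=object)

    out_q: list[np.ndarray] = []
    out_s: list[np.ndarray] = []
    for chrom in np.unique(s_chrom):
        s_mask = s_chrom == chrom
        s_idx = np.flatnonzero(s_mask)
        order = np.argsort(s_start[s_idx], kind="stable")
        s_idx = s_idx[order]
        starts = s_start[s_idx]
        ends = s_end[s_idx]
        max_end = np.maximum.accumulate(ends)

        q_idx = np.flatnonzero(q_chrom == chrom)
        if q_idx.size == 0 or s_idx.size == 0:
            continue
        his = np.searchsorted(starts, q_end[q_idx], side="left")
        los = np.searchsorted(max_end, q_start[q_idx], side="right")
        for qi, lo, hi in zip(q_idx, los, his):
            if lo >= hi:
                continue
            window = slice(lo, hi)
            hit = ends[window] > q_start[qi]
            if hit.any():
                sj = s_idx[window][hit]
                out_q.append(np.full(sj.size, qi, dtype=np.int64))
                out_s.append(sj)
    if not out_q:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    return np.concatenate(out_q), np.concatenate(out_s)


def intervals_to_arrays(
    intervals: Sequence[GenomicInterval],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    chrom = np.asarray([iv.chrom for iv in intervals], dtype=object)
    start = np.asarray([iv.start for iv in intervals], dtype=np.int64)
    end = np.asarray([iv.end for iv in intervals], dtype=np.int64)
    return chrom, start, end
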