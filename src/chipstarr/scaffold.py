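"""Non-redundant region scaffold.

Peaks from all samples are fixed to assay-specific widths (500 bp around the
summit for transcription-factor ChIP, 1000 bp for histone marks), peaks
touching blacklisted features are dropped, the pooled intervals are merged,
and merged blocks wider than 1000 bp are halved recursively. The resulting
disjoint regions (each <= 1000 bp) are the unit of all downstream activity
calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .intervals import (
    GenomicInterval,
    intervals_to_arrays,
    merge_intervals,
    overlap_join,
)
from .io import PeakCall

FIXED_WIDTH = {"TF": 500, "histone": 1000}


@dataclass(frozen=True)
class ScaffoldRegion:
    region_id: str
    interval: GenomicInterval
    parent_merge_id: str

    def __post_init__(self) -> None:
        if self.interval.width > 1000:
            raise ValueError("scaffold regions must be <= 1000 bp")


def fix_peak_width(peak: PeakCall, chrom_size: int | None = None) -> GenomicInterval:
    """Centre a fixed-width interval on the peak summit.

    Width is 500 bp for TF peaks and 1000 bp for histone peaks. At the left
    chromosome edge the window is shifted right to preserve the width; at a
    known right edge (``chrom_size``) it is truncated.
    """
    width = FIXED_WIDTH[peak.assay_class]
    start = peak.summit - width // 2
    end = start + width
    if start < 0:
        start, end = 0, width
    if chrom_size is not None and end > chrom_size:
        end = chrom_size
        start = min(start, end - 1)
    return GenomicInterval(peak.interval.chrom, start, end)


def subtract_blacklist(
    intervals: Sequence[GenomicInterval], blacklist: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Remove (entirely, not trim) every interval overlapping the blacklist
    by at least one base."""
    if not intervals or not blacklist:
        return list(intervals)
    qc, qs, qe = intervals_to_arrays(intervals)
    sc, ss, se = intervals_to_arrays(blacklist)
    hit_q, _ = overlap_join(qc, qs, qe, sc, ss, se)
    hits = set(hit_q.tolist())
    return [iv for i, iv in enumerate(intervals) if i not in hits]


def _halve(start: int, end: int, max_width: int) -> list[tuple[int, int]]:
    """Halve a block to the smallest uniform depth at which every piece fits.

    The whole block is split k times with k minimal such that
    ceil(w / 2^k) <= max_width, the left part of each split getting
    floor(w/2); piece widths therefore differ by at most 1 bp.
    """
    w = end - start
    k = 0
    while w > max_width << k:
        k += 1

    def rec(s: int, e: int, depth: int) -> list[tuple[int, int]]:
        if depth == 0:
            return [(s, e)]
        mid = s + (e - s) // 2
        return rec(s, mid, depth - 1) + rec(mid, e, depth - 1)

    return rec(start, end, k)


def merge_and_split(
    intervals: Iterable[GenomicInterval], max_width: int = 1000
) -> list[ScaffoldRegion]:
    """Merge pooled intervals (book-ended included) and recursively halve
    each merged block until every piece is at most ``max_width``.

    The output tiles each merged block exactly — no gaps, no overlap — and
    region ids are deterministic functions of the sorted order.
    """
    merged = merge_intervals(intervals, book_ended=True)
    regions: list[ScaffoldRegion] = []
    counter = 0
    for j, block in enumerate(merged):
        merge_id = f"merge_{j:06d}"
        for s, e in _halve(block.start, block.end, max_width):
            regions.append(
                ScaffoldRegion(
                    f"region_{counter:06d}",
                    GenomicInterval(block.chrom, s, e),
                    merge_id,
                )
            )
            counter += 1
    return regions


def build_scaffold(
    peaks: Sequence[PeakCall],
    blacklist: Sequence[GenomicInterval] = (),
    max_width: int = 1000,
    fix_widths: bool = True,
    chrom_sizes: dict[str, int] | None = None,
) -> list[ScaffoldRegion]:
    """Full scaffold construction: fix widths, drop blacklisted, merge, split.

    ``fix_widths=False`` merges the raw peak intervals instead (the methods
    order implies fixing first; the alternative is exposed for comparison).
    """
    if fix_widths:
        intervals = [
            fix_peak_width(p, (chrom_sizes or {}).get(p.interval.chrom)) for p in peaks
        ]
    else:
        intervals = [p.interval for p in peaks]
    intervals = subtract_blacklist(intervals, list(blacklist))
    return merge_and_split(intervals, max_width=max_width)


def scaffold_to_frame(regions: Sequence[ScaffoldRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "parent_merge_id": [r.parent_merge_id for r in regions],
        }
    )


def frame_to_scaffold(df: pd.DataFrame) -> list[ScaffoldRegion]:
    parent = df["parent_merge_id"] if "parent_merge_id" in df else df["region_id"]
    return [
        ScaffoldRegion(rid, GenomicInterval(c, int(s), int(e)), pid)
        for rid, c, s, e, pid in zip(df["region_id"], df["chrom"], df["start"], df["end"], parent)
    ]
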