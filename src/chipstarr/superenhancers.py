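"""ROSE-style super-enhancer calling and active-subspace dissection.

H3K27ac peaks are stitched when within 12.5 kb of each other, after removing
peaks fully contained in a 2.5 kb window around any TSS. Stitched enhancers
are ranked by H3K27ac signal over input; with both axes scaled to [0, 1],
the super-enhancer cutoff is the point where the tangent slope of the
ranked curve reaches 1 (equivalently, the rank maximising x - y). The
active subspace of a stitched enhancer is the union of footprints of
overlapping plasmids whose mean RPP reaches the activity threshold theta,
clipped to the enhancer bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals, overlap_join
from .io import PeakCall, TSSRecord

log = logging.getLogger(__name__)

STITCH_DISTANCE = 12_500
TSS_EXCLUSION = 2_500


@dataclass(frozen=True)
class StitchedEnhancer:
    enhancer_id: str
    interval: GenomicInterval
    constituent_peaks: tuple[PeakCall, ...]
    signal: float = float("nan")
    rank: int = -1
    is_super: bool = False


def stitch_peaks(
    peaks: list[PeakCall],
    tss: list[TSSRecord],
    d: int = STITCH_DISTANCE,
    tss_excl: int = TSS_EXCLUSION,
) -> list[StitchedEnhancer]:
    """Stitch peaks within ``d`` bp of each other, excluding TSS-contained peaks.

    A peak is removed only when fully contained in [tss - tss_excl,
    tss + tss_excl] around some TSS (containment, not mere overlap). The
    remaining peaks are merged transitively whenever the gap between
    consecutive peaks is <= d; d=0 merges only overlapping/book-ended peaks.
    Output is sorted and independent of input order.
    """
    if d < 0:
        raise ValueError("stitching distance must be >= 0")
    windows: dict[str, list[tuple[int, int]]] = {}
    for t in tss:
        windows.setdefault(t.chrom, []).append((t.tss - tss_excl, t.tss + tss_excl))

    def excluded(p: PeakCall) -> bool:
        for lo, hi in windows.get(p.interval.chrom, ()):
            if p.interval.start >= lo and p.interval.end <= hi:
                return True
        return False

    kept = sorted(
        (p for p in peaks if not excluded(p)),
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end),
    )
    out: list[StitchedEnhancer] = []
    cluster: list[PeakCall] = []

    def flush() -> None:
        if not cluster:
            return
        start = min(p.interval.start for p in cluster)
        end = max(p.interval.end for p in cluster)
        iv = GenomicInterval(cluster[0].interval.chrom, start, end)
        out.append(
            StitchedEnhancer(f"stitched_{len(out):05d}", iv, tuple(cluster))
        )

    for p in kept:
        if cluster and (
            p.interval.chrom != cluster[-1].interval.chrom
            or p.interval.start - max(c.interval.end for c in cluster) > d
        ):
            flush()
            cluster = []
        cluster.append(p)
    flush()
    return out


def _coverage_sum(
    intervals: list[GenomicInterval], track: pd.DataFrame
) -> np.ndarray:
    """Per-interval sum of value * overlap_length against a bedGraph frame."""
    out = np.zeros(len(intervals), dtype=float)
    if not intervals or track.empty:
        return out
    qc = np.asarray([iv.chrom for iv in intervals], dtype=object)
    qs = np.asarray([iv.start for iv in intervals], dtype=np.int64)
    qe = np.asarray([iv.end for iv in intervals], dtype=np.int64)
    qi, si = overlap_join(
        qc,
        qs,
        qe,
        track["chrom"].to_numpy(object),
        track["start"].to_numpy(np.int64),
        track["end"].to_numpy(np.int64),
    )
    ts = track["start"].to_numpy(np.int64)
    te = track["end"].to_numpy(np.int64)
    tv = track["value"].to_numpy(float)
    for q, s in zip(qi, si):
        ovl = min(qe[q], te[s]) - max(qs[q], ts[s])
        out[q] += ovl * tv[s]
    return out


def enhancer_signal(
    stitched: list[StitchedEnhancer],
    chip: pd.DataFrame,
    input_: pd.DataFrame,
    mode: str = "difference",
) -> np.ndarray:
    """H3K27ac signal per stitched enhancer over its constituent-peak bases.

    'difference' (default): sum of (chip - input) coverage, floored at 0.
    'ratio': sum(chip) / sum(input) (1 + sums when input is empty there).
    """
    if mode not in ("difference", "ratio"):
        raise ValueError("mode must be 'difference' or 'ratio'")
    signals = np.zeros(len(stitched), dtype=float)
    for i, se in enumerate(stitched):
        footprint = merge_intervals([p.interval for p in se.constituent_peaks])
        c = _coverage_sum(footprint, chip).sum()
        b = _coverage_sum(footprint, input_).sum()
        signals[i] = max(c - b, 0.0) if mode == "difference" else (c + 1.0) / (b + 1.0)
    return signals


def superenhancer_cutoff(signals: np.ndarray) -> tuple[int, float]:
    """Rank index and signal value of the slope-1 point of the scaled curve.

    Signals are ranked ascending; both the rank axis and the signal axis are
    scaled to [0, 1]. The cutoff is the rank maximising x - y (the point
    where a slope-1 tangent touches the curve from below); ties break toward
    the higher rank, i.e. fewer super-enhancers. Returns (-1, inf) for
    degenerate curves (< 3 points or no signal spread).
    """
    s = np.sort(np.asarray(signals, dtype=float))
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        return -1, float("inf")
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    diff = x - y
    best = int(np.flatnonzero(diff == diff.max())[-1])
    return best, float(s[best])


def call_super(
    stitched: list[StitchedEnhancer],
    chip: pd.DataFrame,
    input_: pd.DataFrame,
    mode: str = "difference",
) -> list[StitchedEnhancer]:
    """Rank stitched enhancers by signal and flag super-enhancers.

    Enhancers with signal strictly above the slope-1 cutoff value are super.
    With fewer than 3 enhancers or a flat curve none are flagged.
    """
    signals = enhancer_signal(stitched, chip, input_, mode=mode)
    _, cutoff = superenhancer_cutoff(signals)
    if not np.isfinite(cutoff):
        log.warning("degenerate signal curve: no super-enhancers called")
    order = np.argsort(np.argsort(signals, kind="stable"), kind="stable")
    return [
        replace(se, signal=float(sig), rank=int(r), is_super=bool(sig > cutoff))
        for se, sig, r in zip(stitched, signals, order)
    ]


def dissect_active_subspace(
    stitched: list[StitchedEnhancer],
    plasmids: pd.DataFrame,
    theta: float,
) -> pd.DataFrame:
    """Active-subspace metrics per stitched enhancer.

    For each enhancer: the number of overlapping plasmids, how many are
    active (mean RPP >= theta, inclusive), the active fraction, and the
    bases covered by active-plasmid footprints clipped to the enhancer
    (active_bp and its fraction of the enhancer width).
    """
    n = len(stitched)
    rows = []
    if n:
        qc = np.asarray([se.interval.chrom for se in stitched], dtype=object)
        qs = np.asarray([se.interval.start for se in stitched], dtype=np.int64)
        qe = np.asarray([se.interval.end for se in stitched], dtype=np.int64)
        qi, si = overlap_join(
            qc,
            qs,
            qe,
            plasmids["chrom"].to_numpy(object),
            plasmids["start"].to_numpy(np.int64),
            plasmids["end"].to_numpy(np.int64),
        )
        rpp = plasmids["rpp_mean"].to_numpy(float)
        ps = plasmids["start"].to_numpy(np.int64)
        pe = plasmids["end"].to_numpy(np.int64)
        per_enh: dict[int, list[int]] = {}
        for q, s in zip(qi, si):
            per_enh.setdefault(int(q), []).append(int(s))
        for i, se in enumerate(stitched):
            hits = per_enh.get(i, [])
            active = [s for s in hits if rpp[s] >= theta]
            footprints = [
                GenomicInterval(
                    se.interval.chrom,
                    max(ps[s], se.interval.start),
                    min(pe[s], se.interval.end),
                )
                for s in active
            ]
            active_bp = sum(iv.width for iv in merge_intervals(footprints))
            width = se.interval.width
            rows.append(
                {
                    "enhancer_id": se.enhancer_id,
                    "chrom": se.interval.chrom,
                    "start": se.interval.start,
                    "end": se.interval.end,
                    "is_super": se.is_super,
                    "signal": se.signal,
                    "n_plasmids": len(hits),
                    "n_active_plasmids": len(active),
                    "active_fraction": len(active) / len(hits) if hits else np.nan,
                    "active_bp": active_bp,
                    "active_bp_fraction": active_bp / width,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "enhancer_id",
            "chrom",
            "start",
            "end",
            "is_super",
            "signal",
            "n_plasmids",
            "n_active_plasmids",
            "active_fraction",
            "active_bp",
            "active_bp_fraction",
        ],
    )


def se_vs_ne_summary(dissection: pd.DataFrame) -> pd.DataFrame:
    """Aggregate active-subspace metrics for super vs normal enhancers."""
    rows = []
    for label, sub in (
        ("SE", dissection[dissection["is_super"]]),
        ("NE", dissection[~dissection["is_super"]]),
    ):
        width = (sub["end"] - sub["start"]).sum()
        rows.append(
            {
                "group": label,
                "n_enhancers": len(sub),
                "n_plasmids": int(sub["n_plasmids"].sum()),
                "n_active_plasmids": int(sub["n_active_plasmids"].sum()),
                "mean_active_fraction": float(sub["active_fraction"].mean()),
                "total_active_bp": int(sub["active_bp"].sum()),
                "active_bp_fraction": float(sub["active_bp"].sum() / width)
                if width
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
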