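"""Core/extended enhancer modules and region-to-gene assignment.

Active regions overlapping a merged set of previously published predicted
enhancers form the *core* module; active regions with no overlap form the
*extended* module; inactive or unmeasured regions belong to neither. Gene
assignment follows the basal-plus-extension rule: a strand-aware basal
domain of 5 kb upstream / 1 kb downstream of each TSS, extended outward up
to 100 kb but never into a neighbouring gene's basal domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, merge_intervals, overlap_join
from .io import TSSRecord


@dataclass(frozen=True)
class PredictedEnhancerSet:
    """The merged union of one or more published predicted-enhancer sets."""

    source_names: tuple[str, ...]
    intervals: tuple[GenomicInterval, ...]

    @classmethod
    def from_intervals(
        cls, intervals, source_names=("predicted",)
    ) -> "PredictedEnhancerSet":
        return cls(tuple(source_names), tuple(merge_intervals(intervals)))


def partition_modules(
    activity: pd.DataFrame, predicted: PredictedEnhancerSet
) -> pd.DataFrame:
    """Assign each region to the core or extended module (or none).

    ``activity`` is the region table from :func:`chipstarr.activity.region_activity`
    with an 'activity_class' column. Overlap with the predicted set is >= 1 bp.
    """
    pred = list(predicted.intervals)
    overlap = np.zeros(len(activity), dtype=bool)
    if pred:
        pc = np.asarray([iv.chrom for iv in pred], dtype=object)
        ps = np.asarray([iv.start for iv in pred], dtype=np.int64)
        pe = np.asarray([iv.end for iv in pred], dtype=np.int64)
        qi, _ = overlap_join(
            activity["chrom"].to_numpy(object),
            activity["start"].to_numpy(np.int64),
            activity["end"].to_numpy(np.int64),
            pc,
            ps,
            pe,
        )
        overlap[np.unique(qi)] = True
    active = (activity["activity_class"] == "active").to_numpy()
    module = np.where(active & overlap, "core", np.where(active, "extended", "none"))
    out = activity[["region_id"]].copy()
    out["module"] = module
    return out


def regulatory_domains(
    tss: list[TSSRecord],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 100_000,
) -> pd.DataFrame:
    """Basal-plus-extension regulatory domain per gene.

    Basal: [tss - basal_up, tss + basal_down) on '+', mirrored on '-'.
    Extension: outward from the basal edge to the nearer of the neighbouring
    gene's basal boundary or ``max_ext``; a domain always contains its own
    basal domain. Coordinates are clipped at zero.
    """
    rows = []
    for r in tss:
        if r.strand == "+":
            b_start, b_end = r.tss - basal_up, r.tss + basal_down
        else:
            b_start, b_end = r.tss - basal_down + 1, r.tss + basal_up + 1
        rows.append((r.gene_id, r.chrom, r.tss, r.strand, b_start, b_end))
    df = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "tss", "strand", "basal_start", "basal_end"]
    ).sort_values(["chrom", "tss"], kind="stable", ignore_index=True)

    dom_start = np.empty(len(df), dtype=np.int64)
    dom_end = np.empty(len(df), dtype=np.int64)
    for chrom, idx in df.groupby("chrom").groups.items():
        idx = list(idx)
        for k, i in enumerate(idx):
            bs, be = df.at[i, "basal_start"], df.at[i, "basal_end"]
            left_limit = bs - max_ext
            if k > 0:
                left_limit = max(left_limit, df.at[idx[k - 1], "basal_end"])
            right_limit = be + max_ext
            if k + 1 < len(idx):
                right_limit = min(right_limit, df.at[idx[k + 1], "basal_start"])
            dom_start[i] = min(bs, left_limit) if left_limit < bs else left_limit
            dom_end[i] = max(be, right_limit) if right_limit > be else right_limit
            # the domain always contains the basal domain
            dom_start[i] = min(dom_start[i], bs)
            dom_end[i] = max(dom_end[i], be)
    df["domain_start"] = np.maximum(dom_start, 0)
    df["domain_end"] = dom_end
    df["basal_start"] = df["basal_start"].clip(lower=0)
    return df


def signed_tss_distance(start: int, end: int, tss: int, strand: str) -> int:
    """Shortest boundary distance from region [start, end) to the TSS,
    signed so that negative means upstream of the TSS on the gene's strand."""
    if start <= tss < end:
        return 0
    offset = start - tss if tss < start else (end - 1) - tss
    return offset if strand == "+" else -offset


def assign_genes(
    regions: pd.DataFrame,
    tss: list[TSSRecord],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 100_000,
) -> pd.DataFrame:
    """Assign regions to every gene whose regulatory domain they overlap.

    Returns one row per (region, gene) pair with the signed TSS distance
    (negative = upstream of the TSS on the gene's strand).
    """
    domains = regulatory_domains(tss, basal_up, basal_down, max_ext)
    qi, si = overlap_join(
        regions["chrom"].to_numpy(object),
        regions["start"].to_numpy(np.int64),
        regions["end"].to_numpy(np.int64),
        domains["chrom"].to_numpy(object),
        domains["domain_start"].to_numpy(np.int64),
        domains["domain_end"].to_numpy(np.int64),
    )
    rows = []
    for q, s in zip(qi, si):
        start = int(regions["start"].iloc[q])
        end = int(regions["end"].iloc[q])
        rows.append(
            (
                regions["region_id"].iloc[q],
                domains["gene_id"].iloc[s],
                signed_tss_distance(
                    start, end, int(domains["tss"].iloc[s]), domains["strand"].iloc[s]
                ),
            )
        )
    return pd.DataFrame(rows, columns=["region_id", "gene_id", "distance"]).sort_values(
        ["region_id", "gene_id"], kind="stable", ignore_index=True
    )


def tss_proximal_split(
    modules: pd.DataFrame,
    regions: pd.DataFrame,
    tss: list[TSSRecord],
    window: int = 2000,
    module: str = "extended",
) -> tuple[list[str], list[str]]:
    """Split regions of one module into TSS-proximal vs distal sets.

    The distance is the shortest unsigned distance from either region
    boundary to any TSS (zero if a TSS lies inside the region); regions with
    distance <= ``window`` are proximal.
    """
    wanted = set(modules.loc[modules["module"] == module, "region_id"])
    sub = regions[regions["region_id"].isin(wanted)]
    tss_by_chrom: dict[str, np.ndarray] = {}
    for r in tss:
        tss_by_chrom.setdefault(r.chrom, []).append(r.tss)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    proximal, distal = [], []
    for rid, chrom, start, end in zip(
        sub["region_id"], sub["chrom"], sub["start"], sub["end"]
    ):
        sites = tss_by_chrom.get(chrom)
        if sites is None or sites.size == 0:
            distal.append(rid)
            continue
        inside = ((sites >= start) & (sites < end)).any()
        if inside:
            d = 0
        else:
            d = int(
                np.minimum(
                    np.abs(sites - start).min(), np.abs(sites - (end - 1)).min()
                )
            )
        (proximal if d <= window else distal).append(rid)
    return proximal, distal
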