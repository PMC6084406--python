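"""Reads-per-plasmid (RPP) quantification.

A plasmid is identified by the exact genomic coordinates of its cloned
fragment (chrom, start, end). Reporter-RNA fragments are matched to plasmids
only when their coordinates agree exactly; unmatched RNA fragments are
tallied as orphans, never assigned. Counts for each plasmid library and all
RNA samples derived from it are normalised jointly by median-of-ratios size
factors, and the activity of a plasmid is the ratio of normalised RNA to
normalised DNA counts (RPP), averaged over replicates. Region-level activity
is the maximum plasmid-level mean RPP over the plasmids overlapping a
scaffold region.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .intervals import overlap_join

log = logging.getLogger(__name__)

PLASMID_KEY = ["chrom", "start", "end"]


def match_rna_to_plasmids(
    rna: pd.DataFrame, dna: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Match RNA fragments to plasmids by exact (chrom, start, end) identity.

    ``dna`` defines the plasmid universe (one library, one sample). ``rna``
    may contain several samples. Returns a wide count table indexed by the
    plasmid key with one DNA column and one column per RNA sample, plus a
    per-sample tally of orphan RNA counts (fragments with no plasmid at the
    exact same coordinates).
    """
    if dna["sample_id"].nunique() != 1:
        raise ValueError("dna table must contain exactly one sample")
    dna_sample = dna["sample_id"].iloc[0]
    plasmids = dna.set_index(PLASMID_KEY)["count"].rename(dna_sample)
    if not plasmids.index.is_unique:
        raise ValueError("duplicate plasmid keys in DNA table")

    wide = plasmids.to_frame()
    orphans: dict[str, int] = {}
    for sample, sub in rna.groupby("sample_id", sort=True):
        counts = sub.set_index(PLASMID_KEY)["count"]
        matched = counts[counts.index.isin(wide.index)]
        orphans[str(sample)] = int(counts.sum() - matched.sum())
        wide[str(sample)] = matched.reindex(wide.index).fillna(0).astype(np.int64)
    for sample, n in orphans.items():
        if n:
            log.info("sample %s: %d orphan RNA fragment counts", sample, n)
    return wide.sort_index(), orphans


def size_factors(counts: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors, rescaled so their product is 1.

    For sample j: s_j = median over plasmids i of count_ij / g_i, where g_i
    is the geometric mean of plasmid i across samples, taken over plasmids
    with positive counts in every sample. If no plasmid is positive in all
    samples, g_i falls back to the geometric mean over the positive entries
    of plasmid i and the median is taken over positive ratios only.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("counts must be a non-empty 2-D matrix")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (x.sum(axis=0) == 0).any():
        raise ValueError("every sample needs at least one positive count")

    all_pos = (x > 0).all(axis=1)
    if all_pos.any():
        sub = x[all_pos]
        g = np.exp(np.log(sub).mean(axis=1))
        s = np.median(sub / g[:, None], axis=0)
    else:
        any_pos = (x > 0).any(axis=1)
        sub = x[any_pos]
        with np.errstate(divide="ignore"):
            logs = np.where(sub > 0, np.log(np.where(sub > 0, sub, 1.0)), np.nan)
        g = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / g[:, None], np.nan)
        s = np.nanmedian(ratios, axis=0)
        if np.isnan(s).any():
            raise ValueError("size factors undefined: a sample has no usable ratios")
    # product-1 convention keeps single-sample factors at exactly 1
    s = s / np.exp(np.log(s).mean())
    return s


def quantify_library(
    counts: pd.DataFrame, dna_sample: str, rna_samples: list[str]
) -> pd.DataFrame:
    """Per-plasmid normalised counts and per-replicate RPP for one library.

    ``counts`` is the wide table from :func:`match_rna_to_plasmids`. Returns
    a frame indexed by the plasmid key with dna_norm, one rpp_<sample>
    column per replicate, and the across-replicate mean. A replicate in
    which a transfected plasmid yielded no RNA is a measurement of zero, so
    the mean runs over all RNA samples of the library.
    """
    cols = [dna_sample] + list(rna_samples)
    mat = counts[cols].to_numpy(dtype=float)
    s = size_factors(mat)
    norm = mat / s
    dna_norm = norm[:, 0]
    if (dna_norm <= 0).any():
        raise ValueError("plasmid with non-positive normalised DNA count")
    out = pd.DataFrame(index=counts.index)
    out["dna_norm"] = dna_norm
    rpp_cols = []
    for j, sample in enumerate(rna_samples, start=1):
        col = f"rpp_{sample}"
        out[col] = norm[:, j] / dna_norm
        rpp_cols.append(col)
    out["rpp_mean"] = out[rpp_cols].mean(axis=1) if rpp_cols else 0.0
    out["n_replicates"] = len(rna_samples)
    return out


def compute_rpp(fragments: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Plasmid-level mean RPP across all libraries of the fragment table.

    Each plasmid library is normalised jointly with its own RNA samples and
    never with other libraries; comparability across libraries comes only
    through the RPP ratio. When the same plasmid position occurs in several
    libraries its per-replicate RPP values are pooled before averaging.
    Returns a frame with the plasmid key, rpp_mean, the number of replicate
    measurements, and orphan totals in ``attrs``.
    """
    per_replicate: list[pd.DataFrame] = []
    orphan_total = 0
    rna_total = int(
        fragments.loc[
            fragments["sample_id"].isin(
                sheet.loc[sheet["role"] == "reporter_rna", "sample_id"]
            ),
            "count",
        ].sum()
    )
    for library_id, group in sheet.groupby("library_id", sort=True):
        dna_rows = group[group["role"] == "plasmid_dna"]
        if len(dna_rows) != 1:
            raise ValueError(
                f"library {library_id!r} needs exactly one plasmid_dna sample"
            )
        dna_sample = dna_rows["sample_id"].iloc[0]
        rna_samples = (
            group[group["role"] == "reporter_rna"]
            .sort_values("replicate")["sample_id"]
            .tolist()
        )
        dna = fragments[fragments["sample_id"] == dna_sample]
        if dna.empty:
            raise ValueError(f"no fragments for DNA sample {dna_sample!r}")
        rna = fragments[fragments["sample_id"].isin(rna_samples)]
        counts, orphans = match_rna_to_plasmids(rna, dna)
        orphan_total += sum(orphans.values())
        quant = quantify_library(counts, dna_sample, rna_samples)
        long = quant[[f"rpp_{s}" for s in rna_samples]].stack().rename("rpp")
        per_replicate.append(long.reset_index()[PLASMID_KEY + ["rpp"]])

    pooled = pd.concat(per_replicate, ignore_index=True)
    out = (
        pooled.groupby(PLASMID_KEY, as_index=False)
        .agg(rpp_mean=("rpp", "mean"), n_measurements=("rpp", "size"))
        .sort_values(PLASMID_KEY, kind="stable", ignore_index=True)
    )
    out.attrs["orphan_rna_counts"] = orphan_total
    out.attrs["total_rna_counts"] = rna_total
    out.attrs["orphan_rate"] = orphan_total / rna_total if rna_total else 0.0
    return out


def region_activity(
    scaffold: pd.DataFrame, plasmids: pd.DataFrame, theta: float | None = None
) -> pd.DataFrame:
    """Region-level activity: max plasmid mean RPP over overlapping plasmids.

    A plasmid contributes to every scaffold region it overlaps by >= 1 bp.
    Regions without any overlapping plasmid are 'unmeasured'. With a
    threshold theta, regions with rpp_max >= theta are 'active' (inclusive
    boundary), the rest 'inactive'. Ties for the maximum are resolved to the
    first plasmid in (chrom, start, end) order for provenance only.
    """
    plasmids = plasmids.sort_values(PLASMID_KEY, kind="stable", ignore_index=True)
    qi, si = overlap_join(
        scaffold["chrom"].to_numpy(object),
        scaffold["start"].to_numpy(np.int64),
        scaffold["end"].to_numpy(np.int64),
        plasmids["chrom"].to_numpy(object),
        plasmids["start"].to_numpy(np.int64),
        plasmids["end"].to_numpy(np.int64),
    )
    n = len(scaffold)
    rpp_max = np.full(n, np.nan)
    n_plasmids = np.zeros(n, dtype=np.int64)
    top = np.full(n, -1, dtype=np.int64)
    rpp = plasmids["rpp_mean"].to_numpy(float)
    for q, s in zip(qi, si):
        n_plasmids[q] += 1
        if np.isnan(rpp_max[q]) or rpp[s] > rpp_max[q]:
            rpp_max[q] = rpp[s]
            top[q] = s

    out = scaffold[["region_id", "chrom", "start", "end"]].copy()
    out["n_plasmids"] = n_plasmids
    out["rpp_max"] = rpp_max
    key = plasmids[PLASMID_KEY].astype(str)
    labels = (key["chrom"] + ":" + key["start"] + "-" + key["end"]).to_numpy(object)
    out["top_plasmid"] = [labels[t] if t >= 0 else "" for t in top]
    if theta is None:
        cls = np.where(n_plasmids == 0, "unmeasured", "measured")
    else:
        cls = np.where(
            n_plasmids == 0,
            "unmeasured",
            np.where(np.nan_to_num(rpp_max, nan=-np.inf) >= theta, "active", "inactive"),
        )
    out["activity_class"] = cls
    return out
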