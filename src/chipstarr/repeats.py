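"""Observed/expected enrichment of repeat families in region groups.

For each repeat name, overlaps with the full region universe give the
relative frequency f_all = n_overlaps / n_regions; the observed frequency in
a test group, f_test = n_overlap_test / n_test, is compared with f_all to
give O/E = f_test / f_all. The overlap unit is the (region, repeat-copy)
pair: one region hitting k copies of a family counts k. Families with at
most 15 overlaps in the full universe are excluded from interpretation;
O/E > 2 is called enriched and O/E < 0.5 depleted.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import overlap_join
from .io import RepeatRecord

MIN_TOTAL_OVERLAPS = 15  # families with n_overlaps_all <= 15 are excluded
ENRICHED_CUTOFF = 2.0
DEPLETED_CUTOFF = 0.5


def count_overlaps(
    regions: pd.DataFrame,
    repeats: Sequence[RepeatRecord],
    unit: str = "pairs",
) -> dict[str, int]:
    """Count overlaps per repeat_name against a region table.

    ``unit='pairs'`` (default) counts one per overlapping (region, copy)
    pair; ``unit='regions'`` counts each region at most once per family.
    Abutting features (end == start) do not overlap (half-open convention).
    """
    if unit not in ("pairs", "regions"):
        raise ValueError("unit must be 'pairs' or 'regions'")
    if not len(regions) or not repeats:
        return {}
    rc = np.asarray([r.interval.chrom for r in repeats], dtype=object)
    rs = np.asarray([r.interval.start for r in repeats], dtype=np.int64)
    re_ = np.asarray([r.interval.end for r in repeats], dtype=np.int64)
    qi, si = overlap_join(
        regions["chrom"].to_numpy(object),
        regions["start"].to_numpy(np.int64),
        regions["end"].to_numpy(np.int64),
        rc,
        rs,
        re_,
    )
    names = [repeats[s].repeat_name for s in si]
    if unit == "regions":
        pairs = {(q, name) for q, name in zip(qi, names)}
        return dict(Counter(name for _, name in pairs))
    return dict(Counter(names))


def o_over_e(
    all_counts: Mapping[str, int],
    test_counts: Mapping[str, int],
    n_regions: int,
    n_test: int,
    min_total: int = MIN_TOTAL_OVERLAPS,
) -> pd.DataFrame:
    """O/E enrichment table over every repeat name seen in the universe.

    Families whose universe overlap count is <= ``min_total`` get status
    'excluded'; otherwise status is 'enriched' (O/E > 2), 'depleted'
    (O/E < 0.5) or 'neutral'.
    """
    if n_regions <= 0 or n_test <= 0:
        raise ValueError("n_regions and n_test must be positive")
    rows = []
    for name in sorted(all_counts):
        n_all = int(all_counts[name])
        n_ovl_test = int(test_counts.get(name, 0))
        if n_all == 0:
            if n_ovl_test > 0:
                raise ValueError(
                    f"{name}: test overlaps without universe overlaps "
                    "(test group is not a subset of the universe)"
                )
            continue
        f_all = n_all / n_regions
        ratio = (n_ovl_test / n_test) / f_all
        if n_all <= min_total:
            status = "excluded"
        elif ratio > ENRICHED_CUTOFF:
            status = "enriched"
        elif ratio < DEPLETED_CUTOFF:
            status = "depleted"
        else:
            status = "neutral"
        rows.append((name, n_all, f_all, n_test, n_ovl_test, ratio, status))
    return pd.DataFrame(
        rows,
        columns=[
            "repeat_name",
            "n_overlaps_all",
            "f_all",
            "n_test",
            "n_overlap_test",
            "o_over_e",
            "status",
        ],
    )


def enrichment_by_activity_level(
    activity: pd.DataFrame,
    repeats: Sequence[RepeatRecord],
    bins: Sequence[float],
    unit: str = "pairs",
) -> pd.DataFrame:
    """O/E per repeat for nested test groups rpp_max >= threshold.

    ``bins`` are ascending RPP thresholds; each defines a test group of the
    measured regions with rpp_max at or above it. Empty groups yield missing
    values. The universe is the measured regions (rpp_max defined).
    """
    bins = list(bins)
    if any(b > c for b, c in zip(bins, bins[1:])):
        raise ValueError("bins must be ascending")
    universe = activity[activity["n_plasmids"] > 0].reset_index(drop=True)
    all_counts = count_overlaps(universe, repeats, unit=unit)
    out = pd.DataFrame(index=sorted(all_counts), dtype=float)
    out.index.name = "repeat_name"
    for b in bins:
        group = universe[universe["rpp_max"] >= b].reset_index(drop=True)
        col = f"rpp>={b:g}"
        if len(group) == 0:
            out[col] = np.nan
            continue
        counts = count_overlaps(group, repeats, unit=unit)
        table = o_over_e(all_counts, counts, len(universe), len(group))
        out[col] = table.set_index("repeat_name")["o_over_e"]
    return out
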