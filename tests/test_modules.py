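import numpy as np
import pandas as pd
import pytest

from chipstarr.enhancer_modules import (
    PredictedEnhancerSet,
    assign_genes,
    partition_modules,
    regulatory_domains,
    signed_tss_distance,
    tss_proximal_split,
)
from chipstarr.intervals import GenomicInterval
from chipstarr.io import TSSRecord


def activity_frame(rows):
    return pd.DataFrame(
        rows, columns=["region_id", "chrom", "start", "end", "activity_class"]
    )


class TestPartition:
    def test_overlap_gates_on_activity(self):
        act = activity_frame(
            [
                ("r0", "chr1", 100, 600, "active"),
                ("r1", "chr1", 1000, 1500, "active"),
                ("r2", "chr1", 2000, 2500, "inactive"),
                ("r3", "chr1", 3000, 3500, "unmeasured"),
            ]
        )
        pred = PredictedEnhancerSet.from_intervals(
            [GenomicInterval("chr1", 550, 700), GenomicInterval("chr1", 2100, 2300)]
        )
        out = partition_modules(act, pred).set_index("region_id")["module"]
        assert out["r0"] == "core"  # 50 bp overlap
        assert out["r1"] == "extended"
        assert out["r2"] == "none"  # overlaps but inactive
        assert out["r3"] == "none"

    def test_partition_completeness_on_random_input(self):
        rng = np.random.default_rng(4)
        rows = [
            (
                f"r{i}",
                "chr1",
                i * 1000,
                i * 1000 + 500,
                rng.choice(["active", "inactive", "unmeasured"]),
            )
            for i in range(200)
        ]
        act = activity_frame(rows)
        pred = PredictedEnhancerSet.from_intervals(
            [
                GenomicInterval("chr1", int(s), int(s) + 400)
                for s in rng.integers(0, 200_000, 40)
            ]
        )
        out = partition_modules(act, pred)
        n_active = (act["activity_class"] == "active").sum()
        assert (out["module"].isin(["core", "extended"])).sum() == n_active

    def test_published_counts_arithmetic(self):
        """32,353 active regions of which 7,948 overlap the predicted set
        leave an extended module of 24,405."""
        n_active, n_core = 32_353, 7_948
        act = activity_frame(
            [(f"r{i}", "chr1", i * 1000, i * 1000 + 500, "active") for i in range(n_active)]
        )
        pred = PredictedEnhancerSet.from_intervals(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(n_core)]
        )
        out = partition_modules(act, pred)["module"].value_counts()
        assert out.get("core", 0) == n_core
        assert out.get("extended", 0) == 24_405


class TestGeneAssignment:
    def test_region_within_distal_extension_assigned(self):
        tss = [TSSRecord("G", "chr1", 200_000, "+")]
        regions = activity_frame([("r0", "chr1", 150_000, 150_500, "active")])
        out = assign_genes(regions, tss)
        assert list(out["gene_id"]) == ["G"]

    def test_region_beyond_100kb_extension_unassigned(self):
        tss = [TSSRecord("G", "chr1", 200_000, "+")]
        regions = activity_frame([("r0", "chr1", 90_000, 90_500, "active")])
        assert assign_genes(regions, tss).empty

    def test_region_in_two_bidirectional_basal_domains(self):
        tss = [
            TSSRecord("GP", "chr1", 100_000, "+"),
            TSSRecord("GM", "chr1", 100_400, "-"),
        ]
        regions = activity_frame([("r0", "chr1", 100_100, 100_300, "active")])
        out = assign_genes(regions, tss)
        assert sorted(out["gene_id"]) == ["GM", "GP"]

    def test_max_ext_zero_reduces_to_basal_overlap(self):
        tss = [TSSRecord("G", "chr1", 50_000, "+")]
        regions = activity_frame(
            [
                ("in_basal", "chr1", 45_500, 45_700, "active"),
                ("outside", "chr1", 44_000, 44_500, "active"),
            ]
        )
        out = assign_genes(regions, tss, max_ext=0)
        assert list(out["region_id"]) == ["in_basal"]

    def test_distance_sign_is_strand_aware(self):
        # region upstream of the TSS on each strand gets a negative distance
        assert signed_tss_distance(1000, 1500, 2000, "+") == -501
        assert signed_tss_distance(2500, 3000, 2000, "+") == 500
        assert signed_tss_distance(2500, 3000, 2000, "-") == -500
        assert signed_tss_distance(1900, 2100, 2000, "+") == 0

    def test_matches_brute_force_domain_oracle(self):
        rng = np.random.default_rng(17)
        genes = [
            TSSRecord(
                f"G{i}",
                "chr1",
                int(t),
                "+" if rng.random() < 0.5 else "-",
            )
            for i, t in enumerate(np.sort(rng.choice(np.arange(10_000, 900_000, 100), 20, replace=False)))
        ]
        regions = activity_frame(
            [
                (f"r{i}", "chr1", int(s), int(s) + 500, "active")
                for i, s in enumerate(rng.integers(0, 950_000, 200))
            ]
        )
        got = set(
            map(tuple, assign_genes(regions, genes)[["region_id", "gene_id"]].to_numpy())
        )

        # oracle: explicit per-gene domains, then all-pairs overlap loops
        expected = set()
        basal = {}
        for g in genes:
            if g.strand == "+":
                basal[g.gene_id] = (g.tss - 5000, g.tss + 1000)
            else:
                basal[g.gene_id] = (g.tss - 1000 + 1, g.tss + 5000 + 1)
        order = sorted(genes, key=lambda g: g.tss)
        for k, g in enumerate(order):
            bs, be = basal[g.gene_id]
            lo = bs - 100_000
            if k > 0:
                lo = max(lo, basal[order[k - 1].gene_id][1])
            hi = be + 100_000
            if k + 1 < len(order):
                hi = min(hi, basal[order[k + 1].gene_id][0])
            lo, hi = min(lo, bs), max(hi, be)
            for _, rid, _, rs, re_, _ in regions.itertuples():
                if rs < hi and lo < re_:
                    expected.add((rid, g.gene_id))
        assert got == expected


class TestProximalSplit:
    def modules_and_regions(self):
        regions = activity_frame(
            [
                ("near", "chr1", 0, 500, "active"),
                ("far", "chr1", 10_000, 10_500, "active"),
                ("hit", "chr1", 20_000, 20_500, "active"),
            ]
        )
        modules = pd.DataFrame(
            {"region_id": ["near", "far", "hit"], "module": ["extended"] * 3}
        )
        return modules, regions

    def test_boundary_distance_rule(self):
        modules, regions = self.modules_and_regions()
        tss = [
            TSSRecord("A", "chr1", 2_399, "+"),   # 1,900 bp from 'near' end
            TSSRecord("B", "chr1", 12_600, "+"),  # 2,101 bp from 'far' end
            TSSRecord("C", "chr1", 20_250, "+"),  # inside 'hit'
        ]
        proximal, distal = tss_proximal_split(modules, regions, tss, window=2000)
        assert set(proximal) == {"near", "hit"}
        assert set(distal) == {"far"}

    def test_only_requested_module_is_split(self):
        modules, regions = self.modules_and_regions()
        modules.loc[modules["region_id"] == "hit", "module"] = "core"
        proximal, distal = tss_proximal_split(
            modules, regions, [TSSRecord("C", "chr1", 20_250, "+")], window=2000
        )
        assert "hit" not in proximal and "hit" not in distal


def test_regulatory_domains_never_cross_neighbour_basal():
    tss = [TSSRecord("A", "chr1", 50_000, "+"), TSSRecord("B", "chr1", 60_000, "+")]
    doms = regulatory_domains(tss).set_index("gene_id")
    assert doms.loc["A", "domain_end"] == doms.loc["B", "basal_start"]
    assert doms.loc["B", "domain_start"] == doms.loc["A", "basal_end"]
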