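import numpy as np
import pandas as pd
import pytest

from chipstarr import activity as act_mod
from chipstarr.activity import (
    compute_rpp,
    match_rna_to_plasmids,
    quantify_library,
    region_activity,
    size_factors,
)


def frag_table(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_id", "count"])


def brute_size_factors(counts):
    """Independent median-of-ratios: explicit loops, product-1 rescale."""
    counts = np.asarray(counts, dtype=float)
    n, m = counts.shape
    usable = [i for i in range(n) if all(counts[i, j] > 0 for j in range(m))]
    s = []
    for j in range(m):
        ratios = []
        for i in usable:
            g = 1.0
            for k in range(m):
                g *= counts[i, k]
            g = g ** (1.0 / m)
            ratios.append(counts[i, j] / g)
        s.append(float(np.median(ratios)))
    norm = np.prod(s) ** (1.0 / m)
    return np.array([v / norm for v in s])


class TestMatching:
    def test_exact_coordinate_match(self):
        dna = frag_table([("chr1", 100, 321, "D", 1)])
        rna = frag_table([("chr1", 100, 321, "R1", 5)])
        counts, orphans = match_rna_to_plasmids(rna, dna)
        assert counts.loc[("chr1", 100, 321), "R1"] == 5
        assert orphans == {"R1": 0}

    def test_one_bp_mismatch_is_orphan(self):
        dna = frag_table([("chr1", 100, 321, "D", 1)])
        rna = frag_table([("chr1", 101, 321, "R1", 4)])
        counts, orphans = match_rna_to_plasmids(rna, dna)
        assert counts["R1"].sum() == 0
        assert orphans == {"R1": 4}

    def test_no_rna_gives_zero_counts(self):
        dna = frag_table([("chr1", 100, 321, "D", 2), ("chr1", 50, 280, "D", 1)])
        counts, orphans = match_rna_to_plasmids(frag_table([]), dna)
        assert len(counts) == 2 and orphans == {}

    def test_rna_count_conservation(self):
        rng = np.random.default_rng(7)
        dna_rows = [("chr1", int(s), int(s) + 200, "D", 1) for s in rng.integers(0, 5000, 40)]
        rna_rows = [
            ("chr1", int(s), int(s) + 200, "R1", int(c))
            for s, c in zip(rng.integers(0, 5000, 60), rng.integers(1, 9, 60))
        ]
        dna = frag_table(dna_rows).groupby(
            ["chrom", "start", "end", "sample_id"], as_index=False
        )["count"].sum()
        rna = frag_table(rna_rows).groupby(
            ["chrom", "start", "end", "sample_id"], as_index=False
        )["count"].sum()
        counts, orphans = match_rna_to_plasmids(rna, dna)
        assert counts["R1"].sum() + orphans["R1"] == rna["count"].sum()


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        s = size_factors(np.array([[3, 3], [5, 5], [9, 9]]))
        np.testing.assert_allclose(s, [1.0, 1.0])

    def test_doubled_column_splits_symmetrically(self):
        a = np.array([2.0, 4.0, 8.0])
        s = size_factors(np.column_stack([a, 2 * a]))
        np.testing.assert_allclose(s, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_single_sample_is_unity(self):
        np.testing.assert_allclose(size_factors(np.array([[4.0], [7.0]])), [1.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(3, 50))
            m = int(rng.integers(2, 5))
            counts = rng.integers(0, 40, size=(n, m)).astype(float)
            counts[0] = rng.integers(1, 40, size=m)  # keep one all-positive row
            np.testing.assert_allclose(
                size_factors(counts), brute_size_factors(counts), atol=1e-12
            )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(30, 3)).astype(float)
        s0 = size_factors(counts)
        scaled = counts.copy()
        scaled[:, 1] *= 7.0
        s1 = size_factors(scaled)
        # ratios between samples scale with the multiplier
        np.testing.assert_allclose(s1[1] / s1[0], 7.0 * s0[1] / s0[0], rtol=1e-9)
        # normalised counts invariant to a global rescaling
        np.testing.assert_allclose(
            counts / size_factors(counts), (5 * counts) / (5 * size_factors(counts))
        )

    def test_poscounts_fallback_when_no_common_plasmid(self):
        counts = np.array([[4.0, 0.0], [0.0, 6.0], [2.0, 3.0], [0.0, 0.0]])
        counts[2, 0] = 0  # now no row is positive everywhere
        s = size_factors(counts)
        assert np.all(s > 0) and np.isclose(np.prod(s), 1.0)

    def test_matches_pydeseq2_up_to_rescaling(self):
        pydeseq2_dds = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(5)
        # odd row count: pydeseq2 takes the median of log-ratios, which for
        # an even count interpolates geometrically instead of arithmetically
        counts = rng.integers(1, 200, size=(41, 4))
        dds = pydeseq2_dds.DeseqDataSet(
            counts=pd.DataFrame(counts.T),
            metadata=pd.DataFrame({"condition": ["a", "a", "b", "b"]}),
            design="~condition",
            quiet=True,
        )
        dds.fit_size_factors()
        ref = np.asarray(dds.obs["size_factors"], dtype=float)
        ours = size_factors(counts.astype(float))
        np.testing.assert_allclose(ours / ours[0], ref / ref[0], rtol=1e-9)


class TestRPP:
    def test_rpp_ratio_and_replicate_mean(self, monkeypatch):
        # with unit size factors: dna_norm 4, rna (8, 0) -> rpp (2, 0), mean 1
        monkeypatch.setattr(act_mod, "size_factors", lambda m: np.ones(np.asarray(m).shape[1]))
        counts = pd.DataFrame(
            {"D": [4], "R1": [8], "R2": [0]},
            index=pd.MultiIndex.from_tuples([("chr1", 100, 321)], names=["chrom", "start", "end"]),
        )
        out = quantify_library(counts, "D", ["R1", "R2"])
        assert out["dna_norm"].iloc[0] == 4
        assert out["rpp_R1"].iloc[0] == 2 and out["rpp_R2"].iloc[0] == 0
        assert out["rpp_mean"].iloc[0] == 1

    def test_rna_absent_means_zero_rpp(self, monkeypatch):
        monkeypatch.setattr(act_mod, "size_factors", lambda m: np.ones(np.asarray(m).shape[1]))
        counts = pd.DataFrame(
            {"D": [4, 2], "R1": [0, 2]},
            index=pd.MultiIndex.from_tuples(
                [("chr1", 0, 200), ("chr1", 300, 500)], names=["chrom", "start", "end"]
            ),
        )
        out = quantify_library(counts, "D", ["R1"])
        assert out["rpp_mean"].iloc[0] == 0.0

    def test_compute_rpp_matches_brute_force(self):
        rng = np.random.default_rng(23)
        starts = np.sort(rng.choice(np.arange(0, 10_000, 10), size=30, replace=False))
        dna = frag_table([("chr1", int(s), int(s) + 221, "D", int(c)) for s, c in zip(starts, rng.integers(1, 20, 30))])
        rna_rows = []
        for sample in ("R1", "R2", "R3"):
            pick = rng.random(30) < 0.7
            for s, c in zip(starts[pick], rng.integers(1, 30, int(pick.sum()))):
                rna_rows.append(("chr1", int(s), int(s) + 221, sample, int(c)))
        fragments = pd.concat([dna, frag_table(rna_rows)], ignore_index=True)
        sheet = pd.DataFrame(
            {
                "sample_id": ["D", "R1", "R2", "R3"],
                "role": ["plasmid_dna"] + ["reporter_rna"] * 3,
                "library_id": "lib",
                "replicate": [0, 1, 2, 3],
                "cell_state": "primed",
            }
        )
        result = compute_rpp(fragments, sheet).set_index(["chrom", "start", "end"])

        # independent brute force: matrix, median-of-ratios, plain ratios, mean
        wide = fragments.pivot_table(
            index=["chrom", "start", "end"], columns="sample_id", values="count", fill_value=0
        ).loc[[("chr1", int(s), int(s) + 221) for s in starts]]
        s = brute_size_factors(wide[["D", "R1", "R2", "R3"]].to_numpy(float))
        norm = wide[["D", "R1", "R2", "R3"]].to_numpy(float) / s
        expected = (norm[:, 1:] / norm[:, [0]]).mean(axis=1)
        np.testing.assert_allclose(
            result.loc[wide.index, "rpp_mean"].to_numpy(), expected, atol=1e-12
        )


class TestRegionActivity:
    def scaffold(self):
        return pd.DataFrame(
            {
                "region_id": ["r0", "r1", "r2"],
                "chrom": ["chr1"] * 3,
                "start": [0, 1000, 2000],
                "end": [1000, 2000, 3000],
            }
        )

    def plasmids(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "rpp_mean"])

    def test_max_rpp_and_threshold(self):
        plas = self.plasmids(
            [("chr1", 10, 200, 0.0), ("chr1", 50, 260, 3.0), ("chr1", 500, 750, 150.0)]
        )
        out = region_activity(self.scaffold(), plas, theta=138.0)
        r0 = out.set_index("region_id").loc["r0"]
        assert r0["rpp_max"] == 150.0 and r0["activity_class"] == "active"
        assert r0["n_plasmids"] == 3

    def test_region_without_plasmids_is_unmeasured(self):
        out = region_activity(self.scaffold(), self.plasmids([("chr1", 10, 200, 1.0)]), theta=1.0)
        assert out.set_index("region_id").loc["r2", "activity_class"] == "unmeasured"

    def test_threshold_boundary_is_inclusive(self):
        plas = self.plasmids([("chr1", 10, 200, 137.9), ("chr1", 1100, 1300, 138.0)])
        out = region_activity(self.scaffold(), plas, theta=138.0).set_index("region_id")
        assert out.loc["r0", "activity_class"] == "inactive"
        assert out.loc["r1", "activity_class"] == "active"

    def test_spanning_plasmid_counts_in_both_regions(self):
        plas = self.plasmids([("chr1", 900, 1100, 7.0)])
        out = region_activity(self.scaffold(), plas, theta=1.0).set_index("region_id")
        assert out.loc["r0", "rpp_max"] == 7.0 and out.loc["r1", "rpp_max"] == 7.0

    def test_tie_breaks_to_first_plasmid_by_coordinate(self):
        plas = self.plasmids([("chr1", 300, 500, 5.0), ("chr1", 100, 250, 5.0)])
        out = region_activity(self.scaffold(), plas, theta=None)
        assert out["top_plasmid"].iloc[0] == "chr1:100-250"
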