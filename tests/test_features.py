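import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from chipstarr.features import (
    PWM,
    ClassifierConfig,
    dinuc_freq_strandmax,
    extract_features,
    gc_content,
    phastcons_max,
    pwm_null_distribution,
    pwm_threshold,
    read_meme,
    revcomp,
    scan_region,
    train_classifier,
    write_meme,
    DINUCLEOTIDES,
)
from chipstarr.simulate import simulate_feature_matrix


class TestSequenceStats:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("GCNN", 1.0), ("ACGT", 0.5)],
    )
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == expected

    def test_gc_all_n_is_missing(self):
        assert np.isnan(gc_content("NNNN"))

    def test_dinuc_strandmax_homopolymer(self):
        freqs = dict(zip(DINUCLEOTIDES, dinuc_freq_strandmax("AAAA")))
        assert freqs["AA"] == 1.0
        assert freqs["TT"] == 1.0  # reverse complement strand

    def test_dinuc_palindrome_equals_forward(self):
        # ACGT is its own reverse complement
        fwd = dinuc_freq_strandmax("ACGT")
        assert fwd[DINUCLEOTIDES.index("AC")] == pytest.approx(1 / 3)

    def test_dinuc_cg_frequency(self):
        freqs = dict(zip(DINUCLEOTIDES, dinuc_freq_strandmax("CGCG")))
        assert freqs["CG"] == pytest.approx(2 / 3)

    def test_too_short_sequence_missing(self):
        assert np.isnan(dinuc_freq_strandmax("A")).all()


def enumeration_exceedance(pwm, threshold):
    """P(score >= threshold) by brute-force enumeration of all 4^L windows."""
    scores = pwm.int_scores()
    bg = pwm.background
    total = 0.0
    for word in itertools.product(range(4), repeat=len(pwm)):
        s = sum(scores[i, b] for i, b in enumerate(word))
        if s >= threshold:
            total += float(np.prod([bg[b] for b in word]))
    return total


class TestPWMThreshold:
    def random_pwm(self, rng, length):
        return PWM(f"M{length}", rng.dirichlet(np.full(4, 0.5), size=length))

    def test_null_distribution_sums_to_one(self):
        rng = np.random.default_rng(0)
        _, dist = pwm_null_distribution(self.random_pwm(rng, 6))
        assert dist.sum() == pytest.approx(1.0)

    def test_length_one_motif_has_no_hit_at_alpha_005(self):
        pwm = PWM("m1", np.array([[0.97, 0.01, 0.01, 0.01]]))
        t = pwm_threshold(pwm, 0.05)
        # every single base has null exceedance >= 0.25, so none can be a hit
        for base in "ACGT":
            assert scan_region(base, pwm, t) == 0
        assert enumeration_exceedance(pwm, t) < 0.05

    @pytest.mark.parametrize("length", [2, 5, 8])
    def test_dp_exceedance_matches_enumeration(self, length):
        rng = np.random.default_rng(length)
        pwm = self.random_pwm(rng, length)
        for alpha in (0.05, 0.2):
            t = pwm_threshold(pwm, alpha)
            p_at = enumeration_exceedance(pwm, t)
            p_below = enumeration_exceedance(pwm, t - 1)
            assert p_at < alpha <= p_below + 1e-12

    def test_alpha_near_one_accepts_everything(self):
        rng = np.random.default_rng(4)
        pwm = self.random_pwm(rng, 5)
        t = pwm_threshold(pwm, 0.999999)
        assert scan_region("".join(rng.choice(list("ACGT"), 5)), pwm, t) == 1

    def test_invalid_alpha_rejected(self):
        pwm = PWM("m", np.full((3, 4), 0.25))
        with pytest.raises(ValueError):
            pwm_threshold(pwm, 1.5)


class TestScanning:
    def consensus_pwm(self):
        probs = np.full((6, 4), 0.01)
        consensus = "ACGTGA"
        for i, b in enumerate(consensus):
            probs[i, "ACGT".index(b)] = 0.97
        return PWM("cons", probs), consensus

    def test_consensus_is_a_hit(self):
        pwm, consensus = self.consensus_pwm()
        t = pwm_threshold(pwm, 0.05)
        assert scan_region("TTTT" + consensus + "TTTT", pwm, t) == 1

    def test_reverse_complement_only_is_a_hit(self):
        pwm, consensus = self.consensus_pwm()
        t = pwm_threshold(pwm, 0.05)
        assert scan_region("TTTT" + revcomp(consensus) + "TTTT", pwm, t) == 1

    def test_background_sequence_rarely_hits_at_tiny_alpha(self):
        # the p-value bound is per scanned window, so a small alpha is needed
        # for a per-region guarantee: P(any hit) <= alpha * windows * strands
        pwm, _ = self.consensus_pwm()
        t = pwm_threshold(pwm, 5e-4)
        rng = np.random.default_rng(9)
        hits = sum(
            scan_region("".join(rng.choice(list("ACGT"), 40)), pwm, t)
            for _ in range(50)
        )
        assert hits <= 5

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pwm = PWM("m", rng.dirichlet(np.full(4, 0.5), size=7))
            t = pwm_threshold(pwm, 0.1)
            seq = "".join(rng.choice(list("ACGT"), 60))
            assert scan_region(seq, pwm, t) == scan_region(revcomp(seq), pwm, t)

    def test_n_windows_are_skipped(self):
        pwm, consensus = self.consensus_pwm()
        t = pwm_threshold(pwm, 0.05)
        assert scan_region("NNNNNN", pwm, t) == 0


class TestMemeIO:
    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        pwms = [PWM(f"M{i}", rng.dirichlet(np.full(4, 0.5), size=6)) for i in range(2)]
        path = tmp_path / "m.meme"
        write_meme(path, pwms)
        back = read_meme(path)
        assert [m.motif_id for m in back] == ["M0", "M1"]
        np.testing.assert_allclose(back[0].probs, pwms[0].probs, atol=1e-5)


class TestFeatureExtraction:
    def test_phastcons_max_with_missing_coverage(self):
        regions = pd.DataFrame(
            {"region_id": ["a", "b"], "chrom": ["chr1"] * 2, "start": [0, 5000], "end": [1000, 6000]}
        )
        track = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [100, 400], "end": [200, 500], "value": [0.3, 0.9]}
        )
        out = phastcons_max(regions, track)
        np.testing.assert_allclose(out, [0.9, 0.0])

    def test_feature_table_shape_and_determinism(self):
        genome = {"chr1": "ACGT" * 1000}
        regions = pd.DataFrame(
            {"region_id": ["r0", "r1"], "chrom": ["chr1"] * 2, "start": [0, 2000], "end": [500, 2500]}
        )
        pwm = PWM("m", np.full((4, 4), 0.25))
        a = extract_features(regions, genome, None, [pwm])
        b = extract_features(regions, genome, None, [pwm])
        pd.testing.assert_frame_equal(a, b)
        assert {"phastcons_max", "gc", "motif_m"} <= set(a.columns)
        assert sum(c.startswith("dinuc_") for c in a.columns) == 16


class TestClassifierProtocol:
    def test_separable_features_reach_high_auc(self):
        X, y = simulate_feature_matrix(n_samples=300, n_features=60, separation=3.0, seed=1)
        cfg = ClassifierConfig(n_trees=100, n_folds=5, seed=1)
        result = train_classifier(X, y, cfg)
        assert result["auc"] >= 0.95
        top = set(result["importances"].head(5).index)
        assert top <= {f"f{i:03d}" for i in range(5)}

    def test_permuted_labels_give_chance_auc(self):
        rng = np.random.default_rng(2)
        X, y = simulate_feature_matrix(n_samples=300, n_features=60, separation=3.0, seed=2)
        y = rng.permutation(y)
        cfg = ClassifierConfig(n_trees=100, n_folds=5, seed=2)
        assert train_classifier(X, y, cfg)["auc"] == pytest.approx(0.5, abs=0.08)

    def test_features_per_split_clipped_with_warning(self):
        X, y = simulate_feature_matrix(n_samples=120, n_features=10, seed=3)
        cfg = ClassifierConfig(n_trees=20, n_folds=3, features_per_split=50, seed=3)
        with pytest.warns(UserWarning, match="clipping"):
            train_classifier(X, y, cfg)

    def test_single_class_rejected(self):
        X, _ = simulate_feature_matrix(n_samples=50, seed=4)
        with pytest.raises(ValueError, match="two classes"):
            train_classifier(X, np.array(["active"] * 50))

    def test_balancing_downsamples_majority(self):
        X, y = simulate_feature_matrix(n_samples=200, n_features=20, separation=2.0, seed=5)
        y = np.array(["active"] * 160 + ["inactive"] * 40)
        cfg = ClassifierConfig(n_trees=30, n_folds=4, features_per_split=10, seed=5)
        result = train_classifier(X, y, cfg)
        assert 0.0 <= result["auc"] <= 1.0  # protocol runs despite imbalance
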