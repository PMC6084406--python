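"""Sequence features and the enhancer-activity classifier.

Per region: maximum PhastCons conservation, GC content, strand-maximum
dinucleotide frequencies, and binary hits for position weight matrices at an
exact p < 0.05 log-odds threshold. The null score distribution of each PWM
is computed exactly by dynamic programming over an integer-quantised score
histogram under the background model, so the threshold is the smallest score
whose exceedance probability under the background is below alpha. The
classifier is a random forest trained on balanced classes with 10-fold
cross-validation (500 trees, 50 features per split, depth 10).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
DINUCLEOTIDES = [a + b for a in ALPHABET for b in ALPHABET]
QUANT_STEP = 1e-3  # log-odds quantisation for the exact null DP
_PROB_FLOOR = 1e-4


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction over unambiguous bases; N excluded from the denominator.
    Returns NaN for sequences without any A/C/G/T."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in ALPHABET)
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def dinuc_frequencies(seq: str) -> np.ndarray:
    counts = np.zeros(16, dtype=float)
    idx = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    total = 0
    for a, b in zip(seq, seq[1:]):
        i = idx.get(a + b)
        if i is not None:
            counts[i] += 1
            total += 1
    return counts / total if total else np.full(16, np.nan)


def dinuc_freq_strandmax(seq: str) -> np.ndarray:
    """Per-dinucleotide maximum of the forward-strand frequency and the
    frequency on the reverse complement, in AA..TT order."""
    seq = seq.upper()
    if len(seq) < 2:
        return np.full(16, np.nan)
    return np.maximum(dinuc_frequencies(seq), dinuc_frequencies(revcomp(seq)))


@dataclass(frozen=True)
class PWM:
    """A position weight matrix with its background model.

    ``probs`` has one row per motif position over ACGT; rows sum to 1.
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    quality: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must be (length, 4)")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        b = np.asarray(self.background, dtype=float)
        if b.shape != (4,) or not np.isclose(b.sum(), 1.0, atol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    def int_scores(self) -> np.ndarray:
        """Integer-quantised log2-odds scores, shape (length, 4).

        Probabilities are floored at 1e-4 before the log so absent bases get
        a large finite penalty instead of -inf.
        """
        p = np.maximum(np.asarray(self.probs, dtype=float), _PROB_FLOOR)
        b = np.maximum(np.asarray(self.background, dtype=float), _PROB_FLOOR)
        return np.round(np.log2(p / b) / QUANT_STEP).astype(np.int64)

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.probs[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.quality,
        )


def pwm_null_distribution(pwm: PWM) -> tuple[int, np.ndarray]:
    """Exact null distribution of the integer motif score under the background.

    Returns (min_score, probs) where probs[k] = P(score == min_score + k)
    for a random sequence drawn from the background model, computed by
    position-wise convolution of the score histogram.
    """
    scores = pwm.int_scores()
    bg = np.asarray(pwm.background, dtype=float)
    offset = 0
    dist = np.array([1.0])
    for row in scores:
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(dist) + (hi - lo), dtype=float)
        for base in range(4):
            shift = int(row[base]) - lo
            new[shift : shift + len(dist)] += bg[base] * dist
        dist = new
        offset += lo
    return offset, dist


def pwm_threshold(pwm: PWM, alpha: float = 0.05) -> int:
    """Smallest integer score t with P(score >= t | background) < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    offset, dist = pwm_null_distribution(pwm)
    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score >= offset + k)
    above = np.flatnonzero(tail < alpha)
    if above.size:
        return offset + int(above[0])
    return offset + len(dist)  # only scores beyond the maximum qualify


def _window_scores(seq: str, scores: np.ndarray) -> np.ndarray:
    """Integer score of every window of len(pwm) on the given strand;
    windows containing non-ACGT characters score -inf."""
    L = scores.shape[0]
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0)
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(ALPHABET):
        lut[ord(b)] = i
    enc = lut[codes]
    out = np.zeros(n, dtype=float)
    valid = np.ones(n, dtype=bool)
    for pos in range(L):
        window = enc[pos : pos + n]
        ok = window >= 0
        valid &= ok
        out += np.where(ok, scores[pos][np.clip(window, 0, 3)], 0)
    out[~valid] = -np.inf
    return out


def scan_region(seq: str, pwm: PWM, threshold: int) -> int:
    """1 if any window on either strand scores >= threshold, else 0."""
    fwd = _window_scores(seq, pwm.int_scores())
    if fwd.size and bool((fwd >= threshold).any()):
        return 1
    rev = _window_scores(seq, pwm.reverse_complement().int_scores())
    return int(rev.size and bool((rev >= threshold).any()))


def read_meme(path) -> list[PWM]:
    """Read motifs from a MEME (minimal) file via Bio.motifs."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        record = bio_motifs.parse(fh, "minimal")
    bg = record.background or {b: 0.25 for b in ALPHABET}
    background = np.array([bg[b] for b in ALPHABET], dtype=float)
    out = []
    for m in record:
        probs = np.column_stack([np.asarray(m.pwm[b], dtype=float) for b in ALPHABET])
        probs = probs / probs.sum(axis=1, keepdims=True)
        out.append(PWM(m.name or m.consensus, probs, background))
    return out


def write_meme(path, pwms: list[PWM]) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, bg))
            + "\n\n"
        )
        for p in pwms:
            fh.write(f"MOTIF {p.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(p)} "
                f"nsites= 1000000 E= 0\n"
            )
            for row in p.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def phastcons_max(regions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Maximum conservation value overlapping each region; 0 where the
    track has no coverage."""
    from .intervals import overlap_join

    out = np.zeros(len(regions), dtype=float)
    if track.empty or regions.empty:
        return out
    qi, si = overlap_join(
        regions["chrom"].to_numpy(object),
        regions["start"].to_numpy(np.int64),
        regions["end"].to_numpy(np.int64),
        track["chrom"].to_numpy(object),
        track["start"].to_numpy(np.int64),
        track["end"].to_numpy(np.int64),
    )
    vals = track["value"].to_numpy(float)
    for q, s in zip(qi, si):
        if vals[s] > out[q]:
            out[q] = vals[s]
    return out


def extract_features(
    regions: pd.DataFrame,
    genome: dict[str, str],
    conservation: pd.DataFrame | None = None,
    pwms: list[PWM] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Feature table per region: phastcons_max, gc, 16 dinucleotide
    strand-max frequencies, and one binary column per motif."""
    seqs = [
        genome[c][s:e] for c, s, e in zip(regions["chrom"], regions["start"], regions["end"])
    ]
    data = {"region_id": regions["region_id"].to_numpy()}
    data["phastcons_max"] = (
        phastcons_max(regions, conservation)
        if conservation is not None
        else np.zeros(len(regions))
    )
    data["gc"] = [gc_content(s) for s in seqs]
    dinucs = np.vstack([dinuc_freq_strandmax(s) for s in seqs])
    for i, d in enumerate(DINUCLEOTIDES):
        data[f"dinuc_{d}"] = dinucs[:, i]
    for pwm in pwms or []:
        t = pwm_threshold(pwm, alpha)
        data[f"motif_{pwm.motif_id}"] = [scan_region(s, pwm, t) for s in seqs]
    return pd.DataFrame(data)


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 500
    features_per_split: int = 50
    max_depth: int = 10
    n_folds: int = 10
    balance_classes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "features_per_split", "max_depth", "n_folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Downsample the majority class to the minority size."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y[keep]


def train_classifier(
    features: pd.DataFrame, labels: np.ndarray, cfg: ClassifierConfig = ClassifierConfig()
) -> dict:
    """Cross-validated random-forest classification of enhancer activity.

    ``features`` may include a region_id column (ignored for fitting).
    Labels are binary (e.g. active vs inactive). Each training fold is
    class-balanced by downsampling before fitting; the reported AUC and
    balanced accuracy pool the out-of-fold predictions. Feature importances
    come from a final fit on the full balanced data.
    """
    feat = features.drop(columns=["region_id"], errors="ignore")
    X = feat.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y_bin = (y == classes[1]).astype(int)

    mtry = cfg.features_per_split
    if mtry > X.shape[1]:
        warnings.warn(
            f"features_per_split {mtry} > {X.shape[1]} features; clipping",
            stacklevel=2,
        )
        mtry = X.shape[1]

    def make_rf(seed: int) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features=mtry,
            max_depth=cfg.max_depth,
            random_state=seed,
            n_jobs=1,
        )

    rng = np.random.default_rng(cfg.seed)
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    prob = np.zeros(len(y_bin), dtype=float)
    for fold, (train, test) in enumerate(skf.split(X, y_bin)):
        Xt, yt = X[train], y_bin[train]
        if cfg.balance_classes:
            Xt, yt = _balance(Xt, yt, rng)
        rf = make_rf(cfg.seed + fold)
        rf.fit(Xt, yt)
        prob[test] = rf.predict_proba(X[test])[:, 1]

    auc = float(roc_auc_score(y_bin, prob))
    bacc = float(balanced_accuracy_score(y_bin, (prob >= 0.5).astype(int)))

    Xb, yb = (X, y_bin) if not cfg.balance_classes else _balance(X, y_bin, rng)
    final = make_rf(cfg.seed)
    final.fit(Xb, yb)
    importances = pd.Series(
        final.feature_importances_, index=feat.columns, name="importance"
    ).sort_values(ascending=False)
    return {
        "auc": auc,
        "balanced_accuracy": bacc,
        "oof_probabilities": prob,
        "importances": importances,
        "model": final,
        "classes": classes,
    }
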