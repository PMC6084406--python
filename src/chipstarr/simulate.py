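"""Synthetic ChIP-STARR-seq experiments with known ground truth.

The generator emulates the measurement process the pipeline inverts: a toy
genome carries enhancer loci with latent activity multipliers; plasmid
libraries are drawn by random fragmentation around ChIP-enriched loci
(insert sizes around a 221 bp mean); plasmid DNA read counts are multinomial
over plasmid abundances; reporter-RNA counts per plasmid and replicate are
negative-binomial with mean proportional to DNA count x locus activity x a
per-replicate depth distortion. Repeat families are planted with known O/E
in active regions, super-enhancer domains carry a small active sub-interval,
and every output is written in the dialects the I/O module reads. Scale is
roughly a thousand-fold below the real libraries so a full pipeline run
takes seconds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from . import io as sio
from .features import PWM, write_meme
from .intervals import GenomicInterval, overlap_join

CHROM_ENH = "chr1"
CHROM_SE = "chrSE"


@dataclass(frozen=True)
class RepeatFamilyConfig:
    name: str
    repeat_class: str
    n_copies: int
    planted_oe: float  # target O/E of the family in truth-active regions
    copy_width: int = 300


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    # enhancer loci
    n_enhancer_loci: int = 300
    locus_width: int = 1000
    locus_spacing: int = 3000
    fraction_active: float = 0.2
    active_log_mean: float = float(np.log(150.0))
    active_log_sd: float = 1.0
    inactive_log_mean: float = 0.0
    inactive_log_sd: float = 0.4
    # plasmid library and read-out
    n_plasmids: int = 50_000
    insert_mean: float = 221.0
    insert_sd: float = 60.0
    insert_min: int = 100
    insert_max: int = 450
    dna_depth: float = 6.0  # mean DNA reads per plasmid
    n_rna_replicates: int = 2
    rna_scale: float = 0.5
    nb_dispersion: float = 1.0
    orphan_rate: float = 0.02
    # repeats
    repeat_families: tuple[RepeatFamilyConfig, ...] = (
        RepeatFamilyConfig("LTR7", "LTR", 80, 4.0),
        RepeatFamilyConfig("HERVH-int", "LTR", 60, 4.0),
        RepeatFamilyConfig("AluY", "SINE", 100, 1.0),
        RepeatFamilyConfig("L1PA3", "LINE", 80, 1.0),
        RepeatFamilyConfig("MIR", "SINE", 60, 0.5),
        RepeatFamilyConfig("SVA_RARE", "SVA", 10, 1.0),  # stays below n>15
    )
    # super-enhancer zone
    n_se: int = 5
    se_width: int = 40_000
    se_spacing: int = 25_000
    se_n_peaks: int = 6
    se_peak_width: int = 1500
    se_active_fraction: float = 0.03
    se_plasmids_per_se: int = 600
    se_activity: float = 300.0
    n_normal_enhancers: int = 60
    ne_spacing: int = 16_000
    ne_peak_width: int = 1500
    # annotation
    predicted_fraction: float = 0.4
    n_genes: int = 40

    def __post_init__(self) -> None:
        for name in ("fraction_active", "predicted_fraction", "se_active_fraction", "orphan_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_enhancer_loci",
            "locus_width",
            "n_plasmids",
            "n_rna_replicates",
            "n_se",
            "se_width",
            "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.insert_min >= self.insert_max:
            raise ValueError("insert_min must be below insert_max")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=n)])


def _truncnorm_int(
    rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.round(out).astype(np.int64)


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean[pos] * dispersion)
        out[pos] = rng.poisson(lam)
    return out


def simulate_experiment(cfg: SimulationConfig, outdir: str | Path | None = None) -> dict:
    """Generate a full synthetic dataset; optionally write it to ``outdir``.

    Returns a dict with the genome, peak lists, fragment table, sample
    sheet, repeat/TSS/predicted annotations, coverage tracks, motifs, and a
    ``truth`` dict of DataFrames recording every latent quantity.
    """
    rng = np.random.default_rng(cfg.seed)

    # ---- enhancer loci with latent activity -------------------------------
    n = cfg.n_enhancer_loci
    margin = 2000
    centers = margin + cfg.locus_spacing * np.arange(n) + cfg.locus_width // 2
    starts = centers - cfg.locus_width // 2
    ends = starts + cfg.locus_width
    is_active = np.zeros(n, dtype=bool)
    n_active = int(round(cfg.fraction_active * n))
    if n_active:
        is_active[rng.choice(n, size=n_active, replace=False)] = True
    mult = np.where(
        is_active,
        rng.lognormal(cfg.active_log_mean, cfg.active_log_sd, size=n),
        rng.lognormal(cfg.inactive_log_mean, cfg.inactive_log_sd, size=n),
    )
    blacklist_start = int(ends[-1] + 5000)
    blacklist = [GenomicInterval(CHROM_ENH, blacklist_start, blacklist_start + 3000)]
    chr1_size = blacklist_start + 3000 + margin

    loci = pd.DataFrame(
        {
            "locus_id": [f"locus_{i:04d}" for i in range(n)],
            "chrom": CHROM_ENH,
            "start": starts,
            "end": ends,
            "multiplier": mult,
            "is_active": is_active,
        }
    )

    # ---- peaks ------------------------------------------------------------
    tf_peaks: list[sio.PeakCall] = []
    histone_peaks: list[sio.PeakCall] = []
    for i in range(n):
        c = int(centers[i])
        tf_peaks.append(
            sio.PeakCall(
                GenomicInterval(CHROM_ENH, c - 250, c + 250),
                c,
                float(rng.uniform(5, 50)),
                "TF",
                name=f"tf_peak_{i:04d}",
            )
        )
        histone_peaks.append(
            sio.PeakCall(
                GenomicInterval(CHROM_ENH, c - 500, c + 500),
                c,
                float(rng.uniform(5, 50)),
                "histone",
                name=f"h3k27ac_peak_{i:04d}",
            )
        )
    # decoy peaks inside the blacklist region
    for k in range(3):
        c = blacklist_start + 500 + 800 * k
        histone_peaks.append(
            sio.PeakCall(
                GenomicInterval(CHROM_ENH, c - 250, c + 250),
                c,
                5.0,
                "histone",
                name=f"decoy_{k}",
            )
        )

    # ---- super-enhancer zone ---------------------------------------------
    se_rows = []
    se_peaks: list[sio.PeakCall] = []
    ne_peaks: list[sio.PeakCall] = []
    pos = margin
    se_signal = 10.0 + 3.0 * np.arange(cfg.n_se)
    for k in range(cfg.n_se):
        se_start, se_end = pos, pos + cfg.se_width
        step = cfg.se_width // cfg.se_n_peaks
        for j in range(cfg.se_n_peaks):
            c = se_start + step // 2 + j * step
            se_peaks.append(
                sio.PeakCall(
                    GenomicInterval(CHROM_SE, c - cfg.se_peak_width // 2, c + cfg.se_peak_width // 2),
                    c,
                    float(se_signal[k]),
                    "histone",
                    name=f"se{k}_peak{j}",
                )
            )
        # plant the active sub-interval inside the peak span so the stitched
        # domain (which starts/ends at peak boundaries) contains it fully
        sub_w = int(round(cfg.se_active_fraction * cfg.se_width))
        sub_start = int(
            rng.integers(
                se_start + step // 2 + 1000, se_end - step // 2 - 1000 - sub_w
            )
        )
        se_rows.append(
            {
                "se_id": f"se_{k:02d}",
                "chrom": CHROM_SE,
                "start": se_start,
                "end": se_end,
                "sub_start": sub_start,
                "sub_end": sub_start + sub_w,
                "planted_fraction": sub_w / cfg.se_width,
                "signal_level": float(se_signal[k]),
            }
        )
        pos = se_end + cfg.se_spacing
    ne_signal = rng.uniform(1.5, 4.0, size=cfg.n_normal_enhancers)
    for k in range(cfg.n_normal_enhancers):
        c = pos + cfg.ne_peak_width // 2 + 500
        ne_peaks.append(
            sio.PeakCall(
                GenomicInterval(CHROM_SE, c - cfg.ne_peak_width // 2, c + cfg.ne_peak_width // 2),
                c,
                float(ne_signal[k]),
                "histone",
                name=f"ne_peak_{k:03d}",
            )
        )
        pos += cfg.ne_spacing
    chrse_size = pos + margin
    truth_se = pd.DataFrame(se_rows)

    # ---- genome -----------------------------------------------------------
    genome = {
        CHROM_ENH: _random_seq(rng, chr1_size),
        CHROM_SE: _random_seq(rng, chrse_size),
    }

    # ---- TSS annotation ---------------------------------------------------
    tss_records: list[sio.TSSRecord] = []
    prox_loci = rng.choice(n, size=min(30, n), replace=False)
    for g, i in enumerate(sorted(prox_loci)):
        strand = "+" if g % 2 == 0 else "-"
        tss_records.append(
            sio.TSSRecord(f"GENE{g:03d}", CHROM_ENH, int(starts[i] - 1500), strand)
        )
    n_far = max(cfg.n_genes - len(tss_records), 0)
    far_base = blacklist_start + 3000
    for g in range(n_far):
        tss_records.append(
            sio.TSSRecord(
                f"GENEF{g:03d}", CHROM_ENH, int(far_base - 200 - 37 * g), "+"
            )
        )
    # a TSS mid-way through SE 0 with a sacrificial fully-contained peak
    se0 = truth_se.iloc[0]
    tss_se = int((se0["start"] + se0["end"]) // 2)
    tss_records.append(sio.TSSRecord("GENESE000", CHROM_SE, tss_se, "+"))
    se_peaks.append(
        sio.PeakCall(
            GenomicInterval(CHROM_SE, tss_se - 400, tss_se + 400),
            tss_se,
            3.0,
            "histone",
            name="se0_tss_peak",
        )
    )

    # ---- repeats ----------------------------------------------------------
    repeats: list[sio.RepeatRecord] = []
    active_idx = np.flatnonzero(is_active)
    inactive_idx = np.flatnonzero(~is_active)
    f_active = len(active_idx) / n if n else 0.0
    for fam in cfg.repeat_families:
        p_active = min(fam.planted_oe * f_active, 1.0) if f_active else 0.0
        for _ in range(fam.n_copies):
            if active_idx.size and rng.random() < p_active:
                i = int(rng.choice(active_idx))
            else:
                i = int(rng.choice(inactive_idx if inactive_idx.size else np.arange(n)))
            off = int(rng.integers(0, cfg.locus_width - fam.copy_width))
            s = int(starts[i] + off)
            repeats.append(
                sio.RepeatRecord(
                    GenomicInterval(CHROM_ENH, s, s + fam.copy_width),
                    fam.name,
                    fam.repeat_class,
                )
            )
    truth_repeats = pd.DataFrame(
        {
            "repeat_name": [f.name for f in cfg.repeat_families],
            "planted_oe": [f.planted_oe for f in cfg.repeat_families],
            "n_copies": [f.n_copies for f in cfg.repeat_families],
        }
    )

    # ---- predicted-enhancer set ------------------------------------------
    n_pred = int(round(cfg.predicted_fraction * n))
    pred_idx = np.sort(rng.choice(n, size=n_pred, replace=False))
    predicted = [
        GenomicInterval(CHROM_ENH, int(starts[i]), int(ends[i])) for i in pred_idx
    ]
    loci["predicted"] = np.isin(np.arange(n), pred_idx)

    # ---- plasmid library --------------------------------------------------
    locus_weight = rng.gamma(2.0, 1.0, size=n)
    locus_of = rng.choice(n, size=cfg.n_plasmids, p=locus_weight / locus_weight.sum())
    frag_centers = centers[locus_of] + rng.normal(0, 300, size=cfg.n_plasmids)
    inserts = _truncnorm_int(
        rng, cfg.insert_mean, cfg.insert_sd, cfg.insert_min, cfg.insert_max, cfg.n_plasmids
    )
    p_start = np.round(frag_centers - inserts / 2).astype(np.int64)
    p_start = np.clip(p_start, 0, None)
    p_end = p_start + inserts
    p_chrom = np.full(cfg.n_plasmids, CHROM_ENH, dtype=object)
    p_mult = mult[locus_of]

    n_se_plasmids = cfg.n_se * cfg.se_plasmids_per_se
    se_of = np.repeat(np.arange(cfg.n_se), cfg.se_plasmids_per_se)
    se_starts = truth_se["start"].to_numpy()
    se_centers = se_starts[se_of] + rng.uniform(0, cfg.se_width, size=n_se_plasmids)
    se_inserts = _truncnorm_int(
        rng, cfg.insert_mean, cfg.insert_sd, cfg.insert_min, cfg.insert_max, n_se_plasmids
    )
    s_start = np.round(se_centers - se_inserts / 2).astype(np.int64)
    s_end = s_start + se_inserts
    sub_s = truth_se["sub_start"].to_numpy()[se_of]
    sub_e = truth_se["sub_end"].to_numpy()[se_of]
    inside = (s_start >= sub_s) & (s_end <= sub_e)
    s_mult = np.where(inside, cfg.se_activity, 1.0)

    chrom = np.concatenate([p_chrom, np.full(n_se_plasmids, CHROM_SE, dtype=object)])
    start = np.concatenate([p_start, s_start])
    end = np.concatenate([p_end, s_end])
    activity = np.concatenate([p_mult, s_mult])

    plasmids = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": end, "activity": activity}
    )
    # collapse duplicate fragment coordinates (same plasmid position)
    plasmids = plasmids.groupby(["chrom", "start", "end"], as_index=False).agg(
        activity=("activity", "max")
    )
    m = len(plasmids)

    # ---- sequencing read-out ---------------------------------------------
    abundance = rng.gamma(1.5, 1.0, size=m)
    total_dna = int(round(cfg.dna_depth * m))
    dna_counts = rng.multinomial(total_dna, abundance / abundance.sum())
    observed = dna_counts > 0
    plasmids = plasmids.loc[observed].reset_index(drop=True)
    dna_counts = dna_counts[observed]
    m = len(plasmids)

    frames = [
        pd.DataFrame(
            {
                "chrom": plasmids["chrom"],
                "start": plasmids["start"],
                "end": plasmids["end"],
                "sample_id": "dna_lib1",
                "count": dna_counts,
            }
        )
    ]
    depth_factors = rng.lognormal(0.0, 0.2, size=cfg.n_rna_replicates)
    rna_sample_names = [f"rna_lib1_r{r + 1}" for r in range(cfg.n_rna_replicates)]
    act = plasmids["activity"].to_numpy()
    for r, sample in enumerate(rna_sample_names):
        mu = dna_counts * act * cfg.rna_scale * depth_factors[r]
        counts = _negbin(rng, mu, cfg.nb_dispersion)
        nz = counts > 0
        rna = pd.DataFrame(
            {
                "chrom": plasmids.loc[nz, "chrom"],
                "start": plasmids.loc[nz, "start"],
                "end": plasmids.loc[nz, "end"],
                "sample_id": sample,
                "count": counts[nz],
            }
        )
        # orphan RNA fragments at coordinates absent from the plasmid library
        matched_total = int(counts.sum())
        n_orphan = int(round(cfg.orphan_rate / (1 - cfg.orphan_rate) * matched_total))
        if n_orphan:
            key_set = set(
                zip(plasmids["chrom"], plasmids["start"].astype(int), plasmids["end"].astype(int))
            )
            picks = rng.integers(0, m, size=n_orphan)
            rows = []
            for p in picks:
                c = plasmids["chrom"].iat[p]
                s0 = int(plasmids["start"].iat[p])
                e0 = int(plasmids["end"].iat[p])
                shift = 1
                while (c, s0 + shift, e0 + shift) in key_set:
                    shift += 1
                rows.append((c, s0 + shift, e0 + shift, sample, 1))
            rna = pd.concat(
                [rna, pd.DataFrame(rows, columns=sio.FRAGMENT_COLUMNS)],
                ignore_index=True,
            )
        frames.append(rna)
    fragments = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "start", "end", "sample_id"], as_index=False)["count"]
        .sum()
        .sort_values(["chrom", "start", "end", "sample_id"], ignore_index=True)
    )

    sheet = pd.DataFrame(
        {
            "sample_id": ["dna_lib1"] + rna_sample_names,
            "role": ["plasmid_dna"] + ["reporter_rna"] * cfg.n_rna_replicates,
            "library_id": "lib1",
            "replicate": [0] + list(range(1, cfg.n_rna_replicates + 1)),
            "cell_state": "primed",
        }
    )

    # ---- conservation track ----------------------------------------------
    cons_rows = []
    for i in range(n):
        base = rng.beta(8, 3) if is_active[i] else rng.beta(2, 6)
        for b in range(int(starts[i]), int(ends[i]), 200):
            cons_rows.append(
                (CHROM_ENH, b, min(b + 200, int(ends[i])), round(float(np.clip(base + rng.normal(0, 0.05), 0, 1)), 4))
            )
    conservation = pd.DataFrame(cons_rows, columns=["chrom", "start", "end", "value"])

    # ---- H3K27ac / input coverage on the SE chromosome -------------------
    chip_rows = []
    input_rows = []
    all_se_peaks = se_peaks + ne_peaks
    for b in range(0, chrse_size, 200):
        e = min(b + 200, chrse_size)
        val = 1.0
        for p in all_se_peaks:
            if b < p.interval.end and p.interval.start < e:
                val = max(val, p.score)
        chip_rows.append((CHROM_SE, b, e, val))
        input_rows.append((CHROM_SE, b, e, 1.0))
    chip = pd.DataFrame(chip_rows, columns=["chrom", "start", "end", "value"])
    input_track = pd.DataFrame(input_rows, columns=["chrom", "start", "end", "value"])

    # ---- demo motifs ------------------------------------------------------
    motifs = []
    for k in range(3):
        L = int(rng.integers(6, 10))
        probs = rng.dirichlet(np.full(4, 0.3), size=L)
        motifs.append(PWM(f"MOTIF{k}", probs))

    truth = {
        "loci": loci,
        "repeat_families": truth_repeats,
        "super_enhancers": truth_se,
        "config": cfg,
    }
    data = {
        "config": cfg,
        "genome": genome,
        "tf_peaks": tf_peaks,
        "histone_peaks": histone_peaks + se_peaks + ne_peaks,
        "blacklist": blacklist,
        "fragments": fragments,
        "sample_sheet": sheet,
        "repeats": repeats,
        "tss": tss_records,
        "predicted": predicted,
        "conservation": conservation,
        "chip_track": chip,
        "input_track": input_track,
        "motifs": motifs,
        "truth": truth,
    }
    if outdir is not None:
        write_dataset(data, Path(outdir))
    return data


def write_dataset(data: dict, outdir: Path) -> None:
    """Write every simulated component in the pipeline's input dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_fasta(outdir / "genome.fa", data["genome"])
    sio.write_narrowpeak(outdir / "peaks_tf.narrowPeak", data["tf_peaks"])
    sio.write_narrowpeak(outdir / "peaks_h3k27ac.narrowPeak", data["histone_peaks"])
    sio.write_bed(outdir / "blacklist.bed", data["blacklist"])
    sio.write_fragments(outdir / "fragments.tsv", data["fragments"])
    data["sample_sheet"].to_csv(outdir / "samples.tsv", sep="\t", index=False)
    sio.write_repeats(outdir / "repeats.tsv", data["repeats"])
    sio.write_tss_bed(outdir / "tss.bed", data["tss"])
    sio.write_bed(outdir / "predicted.bed", data["predicted"])
    sio.write_bedgraph(outdir / "conservation.bedGraph", data["conservation"])
    sio.write_bedgraph(outdir / "chip_se.bedGraph", data["chip_track"])
    sio.write_bedgraph(outdir / "input_se.bedGraph", data["input_track"])
    write_meme(outdir / "motifs.meme", data["motifs"])
    truth = data["truth"]
    truth["loci"].to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    truth["repeat_families"].to_csv(outdir / "truth_repeats.tsv", sep="\t", index=False)
    truth["super_enhancers"].to_csv(outdir / "truth_se.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(asdict(data["config"]), fh, indent=2, default=str)


def simulate_feature_matrix(
    n_samples: int = 1000,
    n_features: int = 60,
    n_informative: int = 5,
    separation: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Planted-signal feature matrix for classifier protocol checks.

    The first ``n_informative`` features of class 1 are shifted by
    ``separation`` standard deviations; the rest are pure noise.
    """
    rng = np.random.default_rng(seed)
    y = np.array(["inactive"] * (n_samples // 2) + ["active"] * (n_samples - n_samples // 2))
    rng.shuffle(y)
    X = rng.normal(0, 1, size=(n_samples, n_features))
    X[y == "active", :n_informative] += separation
    cols = [f"f{i:03d}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y


def recovery_report(truth: dict, outputs: dict) -> dict:
    """Compare pipeline outputs against the simulation's ground truth.

    ``outputs`` needs 'activity' (region table with rpp_max and
    activity_class) and may include 'theta', 'te' (O/E table over called
    active regions), 'dissection' (stitched-enhancer table), and
    'orphan_rate'. Region-to-locus matching is by coordinate overlap; an
    activity table that shares no regions with the truth is an error.
    """
    loci: pd.DataFrame = truth["loci"]
    activity: pd.DataFrame = outputs["activity"]
    qi, si = overlap_join(
        loci["chrom"].to_numpy(object),
        loci["start"].to_numpy(np.int64),
        loci["end"].to_numpy(np.int64),
        activity["chrom"].to_numpy(object),
        activity["start"].to_numpy(np.int64),
        activity["end"].to_numpy(np.int64),
    )
    if qi.size == 0:
        raise ValueError("no overlap between truth loci and activity regions")
    rpp = activity["rpp_max"].to_numpy(float)
    cls = activity["activity_class"].to_numpy(object)
    locus_rpp = np.full(len(loci), np.nan)
    locus_called = np.zeros(len(loci), dtype=bool)
    for q, s in zip(qi, si):
        if not np.isnan(rpp[s]) and (np.isnan(locus_rpp[q]) or rpp[s] > locus_rpp[q]):
            locus_rpp[q] = rpp[s]
        locus_called[q] |= cls[s] == "active"
    measured = ~np.isnan(locus_rpp)
    report: dict = {"n_loci": int(len(loci)), "n_loci_measured": int(measured.sum())}
    if measured.sum() >= 3:
        rho = scipy.stats.spearmanr(
            loci.loc[measured, "multiplier"], locus_rpp[measured]
        ).statistic
        report["spearman_latent_vs_rpp_max"] = float(rho)
    t = loci["is_active"].to_numpy(bool)
    if measured.any() and t[measured].any() and (~t[measured]).any():
        from sklearn.metrics import balanced_accuracy_score

        report["balanced_accuracy_active"] = float(
            balanced_accuracy_score(t[measured], locus_called[measured])
        )
    if "theta" in outputs and outputs["theta"] is not None:
        report["theta"] = float(outputs["theta"])
    if "te" in outputs and outputs["te"] is not None:
        te = outputs["te"].set_index("repeat_name")
        fams = truth["repeat_families"]
        recovered = {}
        for name, planted in zip(fams["repeat_name"], fams["planted_oe"]):
            if name in te.index:
                recovered[name] = {
                    "planted_oe": float(planted),
                    "recovered_oe": float(te.loc[name, "o_over_e"]),
                    "status": str(te.loc[name, "status"]),
                }
        report["repeat_recovery"] = recovered
    if "dissection" in outputs and outputs["dissection"] is not None:
        dis = outputs["dissection"]
        truth_se = truth["super_enhancers"]
        qi2, si2 = overlap_join(
            truth_se["chrom"].to_numpy(object),
            truth_se["start"].to_numpy(np.int64),
            truth_se["end"].to_numpy(np.int64),
            dis["chrom"].to_numpy(object),
            dis["start"].to_numpy(np.int64),
            dis["end"].to_numpy(np.int64),
        )
        rec = {}
        frac = dis["active_bp_fraction"].to_numpy(float)
        for q, s in zip(qi2, si2):
            sid = truth_se["se_id"].iloc[q]
            rec[sid] = {
                "planted_fraction": float(truth_se["planted_fraction"].iloc[q]),
                "recovered_fraction": float(frac[s]),
            }
        report["se_recovery"] = rec
        if rec:
            errs = [
                abs(v["recovered_fraction"] - v["planted_fraction"]) for v in rec.values()
            ]
            report["se_fraction_mae"] = float(np.mean(errs))
    if "orphan_rate" in outputs and outputs["orphan_rate"] is not None:
        report["orphan_rate_observed"] = float(outputs["orphan_rate"])
        report["orphan_rate_configured"] = float(truth["config"].orphan_rate)
    return report


def read_truth(outdir: Path, cfg: SimulationConfig | None = None) -> dict:
    outdir = Path(outdir)
    truth = {
        "loci": pd.read_csv(outdir / "truth_loci.tsv", sep="\t"),
        "repeat_families": pd.read_csv(outdir / "truth_repeats.tsv", sep="\t"),
        "super_enhancers": pd.read_csv(outdir / "truth_se.tsv", sep="\t"),
    }
    if cfg is None:
        with open(outdir / "sim_config.json") as fh:
            raw = json.load(fh)
        raw["repeat_families"] = tuple(
            RepeatFamilyConfig(**f) for f in raw["repeat_families"]
        )
        for k in ("active_log_mean",):
            raw[k] = float(raw[k])
        cfg = SimulationConfig(**raw)
    truth["config"] = cfg
    return truth
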