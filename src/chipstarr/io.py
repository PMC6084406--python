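"""Readers and writers for the plain-text genomics formats the pipeline touches.

Supported dialects: ENCODE narrowPeak (10 columns), BED3/4/6, a 5-column
fragment table (chrom, frag_start, frag_end, sample_id, count), full 10-column
BEDPE, SAM/BAM fragment input, UCSC RepeatMasker TSV or 5-column BED-like
repeat tables, bedGraph, and FASTA. Everything is normalised to 0-based
half-open coordinates on the way in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

log = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "sample_id", "count"]


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@dataclass(frozen=True)
class PeakCall:
    """A called peak with its summit; ``assay_class`` ('TF' or 'histone')
    determines the fixed width applied downstream (500 vs 1000 bp)."""

    interval: GenomicInterval
    summit: int  # absolute position
    score: float
    assay_class: str
    name: str = "."

    def __post_init__(self) -> None:
        if self.assay_class not in ("TF", "histone"):
            raise ValueError("assay_class must be 'TF' or 'histone'")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    repeat_name: str
    repeat_class: str

    def __post_init__(self) -> None:
        if not self.repeat_name:
            raise ValueError("repeat_name must be non-empty")


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


def read_narrowpeak(path: str | Path, assay_class: str) -> list[PeakCall]:
    """Read an ENCODE narrowPeak file.

    Column 10 is the summit offset from the peak start; the MACS2 convention
    of -1 (no point-source) maps the summit to the interval midpoint.
    """
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) != 10:
                raise FormatError(
                    f"{path}:{lineno}: not narrowPeak (expected 10 columns, got {len(f)})"
                )
            try:
                start, end = int(f[1]), int(f[2])
                score = float(f[4])
                offset = int(f[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {exc}") from exc
            interval = GenomicInterval(f[0], start, end)
            if offset == -1:
                summit = start + interval.width // 2
            else:
                if not 0 <= offset < interval.width:
                    raise FormatError(
                        f"{path}:{lineno}: summit offset {offset} outside interval"
                    )
                summit = start + offset
            peaks.append(PeakCall(interval, summit, score, assay_class, name=f[3]))
    return peaks


def write_narrowpeak(path: str | Path, peaks: Sequence[PeakCall]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{p.score:g}\t.\t"
                f"0\t0\t0\t{p.summit - iv.start}\n"
            )


def read_fragments(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read sequenced paired-end fragments into a fragment table.

    Accepts the package's 5-column fragment table, full 10-column BEDPE
    (fragment = outer span of the two mates; name column = sample id), or
    SAM/BAM. From SAM/BAM only properly paired fragments with both mates on
    the same chromosome at MAPQ >= 30 are kept. Returns one row per distinct
    (chrom, start, end, sample_id) with aggregated counts; the number of
    dropped cross-chromosome BEDPE rows is stored in ``df.attrs``.
    """
    path = Path(path)
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        df = _fragments_from_alignments(path, sample_id)
    else:
        df = _fragments_from_table(path, sample_id)
    if df.empty:
        out = pd.DataFrame(columns=FRAGMENT_COLUMNS)
        out.attrs.update(df.attrs)
        return out
    bad = df["end"] <= df["start"]
    if bad.any():
        raise FormatError(f"{path}: {int(bad.sum())} fragments with end <= start")
    out = (
        df.groupby(["chrom", "start", "end", "sample_id"], as_index=False, sort=True)[
            "count"
        ]
        .sum()
        .astype({"start": np.int64, "end": np.int64, "count": np.int64})
    )
    out.attrs.update(df.attrs)
    return out


def _fragments_from_table(path: Path, sample_id: str | None) -> pd.DataFrame:
    rows = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) == 5:
                rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4])))
            elif len(f) >= 6:  # BEDPE
                if f[0] != f[3]:
                    dropped += 1
                    continue
                start = min(int(f[1]), int(f[4]))
                end = max(int(f[2]), int(f[5]))
                sid = f[6] if len(f) > 6 and f[6] != "." else (sample_id or "sample")
                rows.append((f[0], start, end, sid, 1))
            else:
                raise FormatError(
                    f"{path}:{lineno}: expected 5-column fragment table or BEDPE"
                )
    if dropped:
        log.warning("%s: dropped %d cross-chromosome BEDPE rows", path, dropped)
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    if sample_id is not None and not df.empty:
        df["sample_id"] = sample_id
    df.attrs["n_cross_chrom_dropped"] = dropped
    return df


def _fragments_from_alignments(path: Path, sample_id: str | None) -> pd.DataFrame:
    import pysam

    if sample_id is None:
        sample_id = path.stem
    mode = "rb" if path.suffix.lower() == ".bam" else "r"
    first_mate: dict[str, object] = {}
    rows = []
    with pysam.AlignmentFile(str(path), mode) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_proper_pair:
                continue
            mate = first_mate.pop(read.query_name, None)
            if mate is None:
                first_mate[read.query_name] = read
                continue
            if read.mapping_quality < 30 or mate.mapping_quality < 30:
                continue
            if read.reference_name != mate.reference_name:
                continue
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            rows.append((read.reference_name, start, end, sample_id, 1))
    df = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    df.attrs["n_cross_chrom_dropped"] = 0
    return df


def write_fragments(path: str | Path, df: pd.DataFrame) -> None:
    """Write a fragment table in the canonical sorted 5-column dialect."""
    out = df[FRAGMENT_COLUMNS].sort_values(
        ["chrom", "start", "end", "sample_id"], kind="stable"
    )
    out.to_csv(path, sep="\t", header=False, index=False)


_RMSK_NAME_COLS = {"genoName", "genoStart", "genoEnd", "repName", "repClass"}


def read_repeatmasker(path: str | Path, one_based: bool = False) -> list[RepeatRecord]:
    """Read a UCSC rmsk table (header with genoName/…) or a 5-column
    BED-like table (chrom, start, end, name, class).

    ``one_based=True`` declares 1-based inclusive input coordinates, which
    are converted to 0-based half-open. Duplicate rows are kept: each genomic
    copy of a repeat counts separately downstream.
    """
    records: list[RepeatRecord] = []
    with open(path) as fh:
        header: dict[str, int] | None = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = _fields(line.lstrip("#"))
            if lineno == 1 and _RMSK_NAME_COLS.issubset(f):
                header = {name: i for i, name in enumerate(f)}
                continue
            if header is not None:
                chrom = f[header["genoName"]]
                start = int(f[header["genoStart"]])
                end = int(f[header["genoEnd"]])
                name = f[header["repName"]]
                rclass = f[header["repClass"]]
            elif len(f) == 5:
                chrom, name, rclass = f[0], f[3], f[4]
                start, end = int(f[1]), int(f[2])
            else:
                raise FormatError(
                    f"{path}:{lineno}: unknown repeat dialect; expected UCSC rmsk "
                    "header (genoName genoStart genoEnd … repName repClass) or "
                    "5 columns (chrom, start, end, name, class)"
                )
            if one_based:
                start -= 1
            records.append(
                RepeatRecord(GenomicInterval(chrom, start, end), name, rclass)
            )
    return records


def write_repeats(path: str | Path, repeats: Sequence[RepeatRecord]) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_name}\t{r.repeat_class}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/4/6; strand taken from column 6 when present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(
    path: str | Path,
    intervals: Iterable[GenomicInterval],
    names: Iterable[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_tss_bed(path: str | Path) -> list[TSSRecord]:
    """Read TSS records from BED6 (name = gene id). The TSS is the start of
    the interval on '+' and end-1 on '-'. Gene ids must be unique."""
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 6 or f[5] not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: TSS input must be BED6 with strand")
            gene_id = f[3]
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            start, end = int(f[1]), int(f[2])
            tss = start if f[5] == "+" else end - 1
            records.append(TSSRecord(gene_id, f[0], tss, f[5]))
    return records


def write_tss_bed(path: str | Path, records: Sequence[TSSRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.strand == "+":
                start, end = r.tss, r.tss + 1
            else:
                start, end = r.tss, r.tss + 1
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.gene_id}\t0\t{r.strand}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph into a DataFrame (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "value"],
        comment="#",
        dtype={"chrom": str},
    )
    if df[["start", "end", "value"]].isna().any().any():
        raise FormatError(f"{path}: malformed bedGraph")
    return df


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False, float_format="%g"
    )


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet (TSV with header: sample_id, role, library_id,
    replicate, cell_state). Every reporter_rna sample must name a library
    that has a plasmid_dna sample."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "library_id", "replicate", "cell_state"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    bad_role = ~df["role"].isin(["plasmid_dna", "reporter_rna"])
    if bad_role.any():
        raise FormatError(f"{path}: invalid role values {df.loc[bad_role, 'role'].tolist()}")
    dna_libs = set(df.loc[df["role"] == "plasmid_dna", "library_id"])
    rna_libs = set(df.loc[df["role"] == "reporter_rna", "library_id"])
    orphaned = rna_libs - dna_libs
    if orphaned:
        raise FormatError(f"{path}: RNA samples reference libraries without DNA: {sorted(orphaned)}")
    df["replicate"] = df["replicate"].astype(int)
    return df
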