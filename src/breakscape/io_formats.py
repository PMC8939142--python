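"""Strict readers and writers for the external formats the pipeline touches.

Every reader rejects malformed input with the offending line number rather
than silently coercing; every writer/reader pair round-trips valid records
exactly.  Coordinates are converted to the internal 0-based half-open
convention at this boundary (GTF is 1-based inclusive; BED and the tabular
annotation dialect are already 0-based half-open).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genome_model import BreakSet, GenomicInterval

PWM_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(PWM_ALPHABET)}


class FormatError(ValueError):
    """Malformed external input file."""


# ---------------------------------------------------------------------------
# BED: breaks and scored peaks
# ---------------------------------------------------------------------------

def _bed_records(path: Union[str, Path]) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_bed_coords(fields: List[str], lineno: int, path) -> Tuple[str, int, int]:
    if len(fields) < 3:
        raise FormatError(f"{path}:{lineno}: BED record has fewer than 3 columns")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: non-integer BED coordinate") from exc
    if start < 0:
        raise FormatError(f"{path}:{lineno}: negative start {start}")
    if start >= end:
        raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
    return chrom, start, end


def read_breaks_bed(
    path: Union[str, Path], sample: Optional[str] = None, deduplicate: bool = False
) -> Tuple[BreakSet, int]:
    """Read single-nucleotide DSB coordinates from a BED3+ file.

    Records wider than 1 bp are reduced to their start coordinate; the count
    of such records is returned alongside the BreakSet so callers can warn.
    """
    sample = sample if sample is not None else Path(path).stem
    by_chrom: Dict[str, List[int]] = {}
    n_wide = 0
    for lineno, fields in _bed_records(path):
        chrom, start, end = _parse_bed_coords(fields, lineno, path)
        if end - start > 1:
            n_wide += 1
        by_chrom.setdefault(chrom, []).append(start)
    return BreakSet(sample, by_chrom, deduplicated=deduplicate), n_wide


def write_breaks_bed(breaks: BreakSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for p in breaks.points():
            fh.write(f"{p.chrom}\t{p.pos}\t{p.pos + 1}\n")


def read_peaks_bed(path: Union[str, Path]) -> List[GenomicInterval]:
    """Read scored peaks (BED5: chrom start end name score); order preserved."""
    peaks: List[GenomicInterval] = []
    for lineno, fields in _bed_records(path):
        chrom, start, end = _parse_bed_coords(fields, lineno, path)
        if len(fields) < 5:
            raise FormatError(
                f"{path}:{lineno}: peak record lacks the score column (column 5)"
            )
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise FormatError(
                f"{path}:{lineno}: non-numeric score {fields[4]!r} in column 5"
            ) from exc
        if not np.isfinite(score):
            raise FormatError(f"{path}:{lineno}: non-finite score in column 5")
        strand = fields[5] if len(fields) > 5 else "."
        peaks.append(GenomicInterval(chrom, start, end, strand=strand, score=score))
    return peaks


def write_peaks_bed(peaks: Sequence[GenomicInterval], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = p.score if p.score is not None else 0.0
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score:g}\t{p.strand}\n")


def write_regions_bed(regions, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for iv in regions.intervals():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Gene annotation (GTF or refFlat-like tabular)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """One gene: strand-aware TSS plus the gene-body interval.

    TSS is the 5' end of the gene: body.start on '+', body.end - 1 on '-'
    (0-based coordinates throughout).
    """

    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not (0 <= self.body_start < self.body_end):
            raise ValueError(f"gene {self.gene_id}: invalid body interval")

    @property
    def tss(self) -> int:
        return self.body_start if self.strand == "+" else self.body_end - 1

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.body_start, self.body_end, self.strand)


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_annotation(
    path: Union[str, Path], dialect: str = "tabular"
) -> List[GeneRecord]:
    """Read a gene annotation into per-gene records.

    ``tabular``: 5+ columns (gene_id, chrom, strand, txStart, txEnd), 0-based
    half-open.  ``gtf``: standard 1-based inclusive GTF; transcripts are
    collapsed to each gene's outermost bounds so there is one TSS per gene.
    Duplicate gene ids are an error in the tabular dialect.
    """
    if dialect == "tabular":
        return _read_tabular_annotation(path)
    if dialect == "gtf":
        return _read_gtf_annotation(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_tabular_annotation(path) -> List[GeneRecord]:
    genes: List[GeneRecord] = []
    seen: Dict[str, int] = {}
    for lineno, fields in _bed_records(path):
        if len(fields) < 5:
            raise FormatError(f"{path}:{lineno}: expected >=5 columns")
        gene_id, chrom, strand = fields[0], fields[1], fields[2]
        if strand not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
        if gene_id in seen:
            raise FormatError(
                f"{path}:{lineno}: duplicate gene id {gene_id!r} "
                f"(first at line {seen[gene_id]})"
            )
        seen[gene_id] = lineno
        genes.append(GeneRecord(gene_id, chrom, strand, start, end))
    return genes


def _read_gtf_annotation(path) -> List[GeneRecord]:
    # Collapse all features of a gene_id to the outermost 0-based bounds.
    bounds: Dict[str, List] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GTF record has <9 columns")
            chrom, _, _, start_s, end_s, _, strand = fields[:7]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            m = _GTF_GENE_ID.search(fields[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gid = m.group(1)
            start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if gid not in bounds:
                bounds[gid] = [chrom, strand, start0, end0]
            else:
                rec = bounds[gid]
                if rec[0] != chrom or rec[1] != strand:
                    raise FormatError(
                        f"{path}:{lineno}: gene {gid!r} spans chromosomes/strands"
                    )
                rec[2] = min(rec[2], start0)
                rec[3] = max(rec[3], end0)
    return [
        GeneRecord(gid, chrom, strand, s, e)
        for gid, (chrom, strand, s, e) in bounds.items()
    ]


def write_gene_annotation(genes: Sequence[GeneRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.body_start}\t{g.body_end}\n")


# ---------------------------------------------------------------------------
# Expression table (TSV: gene rows, sample columns)
# ---------------------------------------------------------------------------

class ExpressionTable:
    """Gene x sample matrix of non-negative FPKM-like expression values."""

    def __init__(self, df: pd.DataFrame):
        if df.isna().any().any():
            raise FormatError("expression table contains missing cells")
        if (df.to_numpy() < 0).any():
            raise FormatError("expression table contains negative values")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids in expression table: {dups}")
        self.df = df.astype(float)

    @property
    def genes(self) -> List[str]:
        return list(self.df.index)

    @property
    def samples(self) -> List[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def sample_values(self, sample: str) -> pd.Series:
        if sample not in self.df.columns:
            raise KeyError(f"sample {sample!r} not in expression table")
        return self.df[sample]


def read_expression_table(path: Union[str, Path]) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionTable(df)


def write_expression_table(table: ExpressionTable, path: Union[str, Path]) -> None:
    table.df.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path: Union[str, Path]) -> List[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

@dataclass
class MotifPWM:
    """Position frequency matrix over A,C,G,T (rows) x positions (columns)."""

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PWM counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if (self.counts < 0).any():
            raise ValueError("PWM counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("every PWM column must have positive total count")

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    def consensus(self) -> str:
        return "".join(PWM_ALPHABET[i] for i in self.counts.argmax(axis=0))


_PFM_ROW = re.compile(r"^([ACGT])\s*\[?\s*([-0-9.eE+\s]*?)\s*\]?\s*$")


def read_pwm_jaspar(path: Union[str, Path]) -> MotifPWM:
    """Read a JASPAR-layout PFM: '>' header line then four base rows.

    Rows may be bracketed (``A [ 1 2 3 ]``) or bare.  All four bases must be
    present with equal row lengths.
    """
    name = Path(path).stem
    rows: Dict[str, List[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].split() else name
                continue
            m = _PFM_ROW.match(line)
            if not m:
                raise FormatError(f"{path}:{lineno}: unrecognised PFM row")
            base, values = m.group(1), m.group(2).split()
            try:
                rows[base] = [float(v) for v in values]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric PFM count") from exc
    missing = [b for b in PWM_ALPHABET if b not in rows]
    if missing:
        raise FormatError(f"{path}: missing PFM rows for {missing}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: PFM rows have unequal lengths {sorted(lengths)}")
    counts = np.array([rows[b] for b in PWM_ALPHABET], dtype=float)
    return MotifPWM(name=name, counts=counts)


def write_pwm_jaspar(pwm: MotifPWM, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for i, base in enumerate(PWM_ALPHABET):
            row = " ".join(f"{v:g}" for v in pwm.counts[i])
            fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# FASTA sequence access
# ---------------------------------------------------------------------------

class SequenceSource:
    """Uniform fetch(chrom, start, end) over a FASTA file or in-memory dict.

    Sequences are uppercase-normalised; out-of-range fetches raise.  FASTA
    files are accessed through pyfaidx so only the requested slice is read.
    """

    def __init__(self, source: Union[str, Path, Mapping[str, str]]):
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(source), sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {c: s.upper() for c, s in source.items()}

    @property
    def chroms(self) -> List[str]:
        if self._dict is not None:
            return sorted(self._dict)
        return sorted(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > self.length(chrom) or start >= end:
            raise ValueError(
                f"fetch [{start}, {end}) out of range for {chrom} "
                f"(length {self.length(chrom)})"
            )
        if self._dict is not None:
            return self._dict[chrom][start:end]
        return str(self._fasta[chrom][start:end]).upper()


def write_fasta(sequences: Mapping[str, str], path: Union[str, Path], width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
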