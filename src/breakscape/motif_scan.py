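"""PWM scanning for androgen response elements (and other motifs).

Log-odds scores are built from a position frequency matrix with a
pseudocount split by background frequency, then every window of each
region is scored on both strands; windows containing N are unscoreable and
skipped.  The reported threshold is a fraction of the normalised score
range (min..max achievable), so threshold 1.0 reports consensus-exact
matches only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome_model import GenomicInterval, RegionSet
from .io_formats import MotifPWM, SequenceSource

UNIFORM_BACKGROUND = np.full(4, 0.25)
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class MotifHit:
    """One motif match in genome coordinates (end - start = motif length)."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.score)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to int codes A=0 C=1 G=2 T=3, anything else 4 (N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def pwm_logodds(
    pwm: MotifPWM,
    pseudocount: float = 0.8,
    background: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """4 x L log2-odds matrix: log2(((n_b + pc*bg_b)/(N + pc)) / bg_b)."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    counts = pwm.counts
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("PWM has a zero-total column")
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)[None, :]
    return np.log2(probs / bg[:, None])


def score_range(matrix: np.ndarray) -> Tuple[float, float]:
    """(min, max) achievable total log-odds over all sequences of length L."""
    return float(matrix.min(axis=0).sum()), float(matrix.max(axis=0).sum())


def _window_scores(codes: np.ndarray, matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Total score for every window start; validity mask excludes N windows."""
    L = matrix.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    is_n = codes == 4
    safe = np.where(is_n, 0, codes)
    scores = np.zeros(n)
    for j in range(L):
        scores += matrix[safe[j : j + n], j]
    # a window is valid iff it contains no N
    bad = is_n.astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (cum[L:] - cum[:-L]) == 0
    return scores, valid


def _revcomp_matrix(matrix: np.ndarray) -> np.ndarray:
    return matrix[[3, 2, 1, 0], :][:, ::-1]


def scan_sequence(
    seq: str,
    matrix: np.ndarray,
    threshold: float,
    chrom: str = "",
    offset: int = 0,
    both_strands: bool = True,
) -> List[MotifHit]:
    """Report every window scoring >= threshold; minus-strand hits score the
    reverse complement but are reported in forward coordinates.

    The comparison allows a 1e-9 absolute tolerance so that a threshold set
    to the exact achievable maximum (consensus-only scans) is not defeated
    by floating-point summation order.
    """
    codes = encode_sequence(seq)
    L = matrix.shape[1]
    hits: List[MotifHit] = []
    strand_matrices = [("+", matrix)]
    if both_strands:
        strand_matrices.append(("-", _revcomp_matrix(matrix)))
    for strand, m in strand_matrices:
        scores, valid = _window_scores(codes, m)
        for i in np.nonzero(valid & (scores >= threshold - 1e-9))[0]:
            hits.append(
                MotifHit(chrom, offset + int(i), offset + int(i) + L, strand, float(scores[i]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_regions(
    regions: RegionSet,
    fasta: SequenceSource,
    pwm: MotifPWM,
    threshold_fraction: float = 0.8,
    pseudocount: float = 0.8,
    background: Optional[Sequence[float]] = None,
    both_strands: bool = True,
) -> Tuple[List[MotifHit], int]:
    """Scan every region on both strands; returns (hits, n_regions_too_short).

    The score threshold is min + threshold_fraction * (max - min) where
    min/max are the achievable log-odds extremes of the matrix.
    """
    if not (0 < threshold_fraction <= 1):
        raise ValueError("threshold_fraction must be in (0, 1]")
    matrix = pwm_logodds(pwm, pseudocount=pseudocount, background=background)
    lo, hi = score_range(matrix)
    threshold = lo + threshold_fraction * (hi - lo)
    hits: List[MotifHit] = []
    n_short = 0
    for iv in regions.intervals():
        if iv.width < pwm.length:
            n_short += 1
            continue
        seq = fasta.fetch(iv.chrom, iv.start, iv.end)
        hits.extend(
            scan_sequence(seq, matrix, threshold, chrom=iv.chrom, offset=iv.start,
                          both_strands=both_strands)
        )
    return hits, n_short


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    """BED6 with the log-odds score in column 5."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\tare{i}\t{h.score:.4f}\t{h.strand}\n")
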