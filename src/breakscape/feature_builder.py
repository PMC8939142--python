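"""Regulatory feature classes: promoters, enhancers, insulators, ARE partition.

Definitions follow the prostate-cancer regulatory-landscape convention:
promoters are TSS +/- 2 kb of expressed genes; enhancers are the top-N
H3K27ac peaks lying entirely more than 2 kb from any known TSS; insulators
are the top-N CTCF peaks overlapping neither; and each promoter/enhancer is
ARE-positive if it contains at least one androgen-response-element motif
hit (decided by the hit's start coordinate so the partition is exact).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .genome_model import (
    GenomicInterval,
    RegionSet,
    merge,
    merge_region_sets,
)
from .io_formats import ExpressionTable, GeneRecord
from .motif_scan import MotifHit

log = logging.getLogger(__name__)


@dataclass
class FeatureClasses:
    """The four ARE-partitioned range sets plus their parents and insulators."""

    promoters: RegionSet
    enhancers: RegionSet
    insulators: RegionSet
    are_positive_promoters: RegionSet
    are_negative_promoters: RegionSet
    are_positive_enhancers: RegionSet
    are_negative_enhancers: RegionSet

    def four_sets(self) -> Dict[str, RegionSet]:
        return {
            "ARE+ promoters": self.are_positive_promoters,
            "ARE- promoters": self.are_negative_promoters,
            "ARE+ enhancers": self.are_positive_enhancers,
            "ARE- enhancers": self.are_negative_enhancers,
        }


def define_promoters(
    genes: Sequence[GeneRecord],
    expression: ExpressionTable,
    sample: str,
    expression_threshold: float = 1.0,
    flank_bp: int = 2000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> RegionSet:
    """TSS +/- flank windows of genes expressed at/above threshold, merged."""
    if flank_bp <= 0:
        raise ValueError(f"flank_bp must be positive, got {flank_bp}")
    expr = expression.sample_values(sample)
    ivals: List[GenomicInterval] = []
    for g in genes:
        if g.gene_id not in expr.index:
            continue
        if expr[g.gene_id] < expression_threshold:
            continue
        start = max(0, g.tss - flank_bp)
        end = g.tss + flank_bp
        if chrom_lengths is not None and g.chrom in chrom_lengths:
            end = min(end, chrom_lengths[g.chrom])
        ivals.append(GenomicInterval(g.chrom, start, end))
    if not ivals:
        raise ValueError(
            "no gene passes the expression threshold "
            f"({expression_threshold}); check the threshold and sample name"
        )
    return merge(ivals, name="promoters")


def _rank_peaks(peaks: Sequence[GenomicInterval], top_n: int, label: str) -> List[GenomicInterval]:
    """Top-N peaks by descending score, ties broken by (chrom, start)."""
    for p in peaks:
        if p.score is None:
            raise ValueError(f"{label}: peak {p.chrom}:{p.start}-{p.end} lacks a score")
    ranked = sorted(peaks, key=lambda p: (-p.score, p.chrom, p.start))
    if len(ranked) < top_n:
        log.warning("%s: only %d eligible peaks for top_n=%d", label, len(ranked), top_n)
    return ranked[:top_n]


def define_enhancers(
    h3k27ac_peaks: Sequence[GenomicInterval],
    all_tss: Sequence[Tuple[str, int]],
    top_n: int = 25000,
    min_tss_distance_bp: int = 2000,
) -> RegionSet:
    """Top-N distal H3K27ac peaks: the filter (every peak edge strictly more
    than min_tss_distance_bp from every TSS) is applied before ranking."""
    tss_by_chrom: Dict[str, np.ndarray] = {}
    for chrom, pos in all_tss:
        tss_by_chrom.setdefault(chrom, []).append(pos)  # type: ignore[union-attr]
    tss_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}

    def distal(p: GenomicInterval) -> bool:
        tss = tss_by_chrom.get(p.chrom)
        if tss is None or tss.size == 0:
            return True
        # nearest TSS to the peak: distance from the nearest edge to the TSS point
        i = np.searchsorted(tss, p.start)
        for j in (i - 1, i, i + 1):
            if 0 <= j < tss.size:
                t = int(tss[j])
                if p.start - min_tss_distance_bp <= t <= p.end - 1 + min_tss_distance_bp:
                    return False
        return True

    eligible = [p for p in h3k27ac_peaks if distal(p)]
    if not eligible:
        log.warning("enhancers: all peaks are TSS-proximal; empty enhancer set")
        return RegionSet("enhancers", {})
    return merge(_rank_peaks(eligible, top_n, "enhancers"), name="enhancers")


def define_insulators(
    ctcf_peaks: Sequence[GenomicInterval],
    promoters: RegionSet,
    enhancers: RegionSet,
    top_n: int = 50000,
) -> RegionSet:
    """Top-N CTCF peaks with zero base overlap with promoters or enhancers
    (half-open: an abutting peak shares no base and is retained)."""

    def overlaps(p: GenomicInterval, rs: RegionSet) -> bool:
        starts, ends = rs.bounds(p.chrom)
        if starts.size == 0:
            return False
        i = int(np.searchsorted(starts, p.end, side="left"))
        # any region starting before p.end whose end exceeds p.start overlaps
        return bool(i > 0 and ends[:i].max() > p.start)

    eligible = [
        p for p in ctcf_peaks if not overlaps(p, promoters) and not overlaps(p, enhancers)
    ]
    if not eligible:
        log.warning("insulators: every CTCF peak overlaps a promoter/enhancer")
        return RegionSet("insulators", {})
    return merge(_rank_peaks(eligible, top_n, "insulators"), name="insulators")


def partition_by_are(
    regions: RegionSet,
    are_hits: Sequence[Union[MotifHit, GenomicInterval]],
) -> Tuple[RegionSet, RegionSet]:
    """Split a merged region set into ARE+ (>=1 hit start inside) and ARE-.

    Membership follows the hit's start coordinate, so a hit straddling a
    region boundary belongs to exactly one region and the two halves of the
    partition conserve total_bp exactly.
    """
    starts_by_chrom: Dict[str, List[int]] = {}
    for h in are_hits:
        starts_by_chrom.setdefault(h.chrom, []).append(h.start)
    hit_starts = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in starts_by_chrom.items()}

    pos_ivals: List[GenomicInterval] = []
    neg_ivals: List[GenomicInterval] = []
    for iv in regions.intervals():
        hs = hit_starts.get(iv.chrom)
        if hs is not None and np.searchsorted(hs, iv.start) < np.searchsorted(hs, iv.end):
            pos_ivals.append(iv)
        else:
            neg_ivals.append(iv)
    base = regions.name or "regions"
    return (
        merge(pos_ivals, name=f"ARE+ {base}"),
        merge(neg_ivals, name=f"ARE- {base}"),
    )


def build_features(
    genes: Sequence[GeneRecord],
    expression: ExpressionTable,
    sample: str,
    h3k27ac_peaks: Sequence[GenomicInterval],
    ctcf_peaks: Sequence[GenomicInterval],
    are_hits: Sequence[Union[MotifHit, GenomicInterval]],
    expression_threshold: float = 1.0,
    promoter_flank_bp: int = 2000,
    enhancer_top_n: int = 25000,
    insulator_top_n: int = 50000,
    min_tss_distance_bp: int = 2000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> FeatureClasses:
    """Build all feature classes and the ARE partition in one pass."""
    promoters = define_promoters(
        genes, expression, sample,
        expression_threshold=expression_threshold,
        flank_bp=promoter_flank_bp,
        chrom_lengths=chrom_lengths,
    )
    all_tss = [(g.chrom, g.tss) for g in genes]
    enhancers = define_enhancers(
        h3k27ac_peaks, all_tss, top_n=enhancer_top_n,
        min_tss_distance_bp=min_tss_distance_bp,
    )
    insulators = define_insulators(ctcf_peaks, promoters, enhancers, top_n=insulator_top_n)
    are_pos_prom, are_neg_prom = partition_by_are(promoters, are_hits)
    are_pos_enh, are_neg_enh = partition_by_are(enhancers, are_hits)
    return FeatureClasses(
        promoters=promoters,
        enhancers=enhancers,
        insulators=insulators,
        are_positive_promoters=are_pos_prom,
        are_negative_promoters=are_neg_prom,
        are_positive_enhancers=are_pos_enh,
        are_negative_enhancers=are_neg_enh,
    )
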