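"""DSB enrichment statistics.

Implements the downstream break-coordinate analyses: between-sample overlap
fractions under widening windows, per-kb break densities over region
classes (the ARE+/ARE- four-set comparison), strand-oriented metagene
profiles around TSSs and TF binding sites, genes-with-break counts, and
motif-proximity fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .feature_builder import FeatureClasses
from .genome_model import (
    BreakSet,
    GenomicInterval,
    RegionSet,
    count_overlaps,
    extend_breaks,
    merge,
)
from .io_formats import ExpressionTable, GeneRecord
from .motif_scan import MotifHit


@dataclass(frozen=True)
class DensityResult:
    """Breaks per kb over a region set; exact integers retained."""

    region_set_name: str
    break_count: int
    total_bp: int

    @property
    def density_per_kb(self) -> float:
        return self.break_count / (self.total_bp / 1000.0)


@dataclass
class TssProfile:
    """Binned break counts around centred anchors, oriented by strand.

    ``bins`` counts each break once per anchor whose window contains it
    (metagene convention); ``per_100kb`` counts each break once over the
    merged union of the windows, scaled to events per 100,000 bp;
    ``per_100kb_per_anchor`` uses the unmerged per-anchor total instead.
    """

    window_bp: int
    bin_bp: int
    bins: np.ndarray
    n_anchors: int
    per_100kb: float
    per_100kb_per_anchor: float

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(-self.window_bp, self.window_bp + 1, self.bin_bp)

    @property
    def total_in_bins(self) -> int:
        return int(self.bins.sum())


def sample_overlap_fraction(query: BreakSet, target: BreakSet, window_bp: int) -> float:
    """Fraction of query breaks whose centred window contains >=1 target break.

    window_bp is the total window width (an "8 nt window" spans 4 bases each
    side of the half-open break point); window 0 demands exact coincidence.
    """
    if len(query) == 0:
        raise ValueError("overlap fraction undefined for an empty query break set")
    if window_bp < 0 or window_bp % 2:
        raise ValueError(f"window_bp must be even and non-negative, got {window_bp}")
    half = window_bp // 2
    n_hit = 0
    for chrom in query.chroms:
        q = query.positions(chrom)
        t = target.positions(chrom)
        if t.size == 0:
            continue
        lo = np.searchsorted(t, q - half, side="left")
        hi = np.searchsorted(t, q + max(half, 1), side="left")
        n_hit += int((hi > lo).sum())
    return n_hit / len(query)


def break_density(breaks: BreakSet, regions: RegionSet) -> DensityResult:
    if regions.total_bp <= 0:
        raise ValueError(f"region set {regions.name!r} has zero total length")
    return DensityResult(
        region_set_name=regions.name,
        break_count=count_overlaps(breaks, regions),
        total_bp=regions.total_bp,
    )


def four_set_density(breaks: BreakSet, features: FeatureClasses) -> Dict[str, DensityResult]:
    """Per-kb densities over ARE+/ARE- promoters and enhancers."""
    return {name: break_density(breaks, rs) for name, rs in features.four_sets().items()}


def density_table(results: Mapping[str, DensityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_set": list(results),
            "break_count": [r.break_count for r in results.values()],
            "total_bp": [r.total_bp for r in results.values()],
            "density_per_kb": [r.density_per_kb for r in results.values()],
        }
    )


def _profile(
    breaks: BreakSet,
    anchors: Sequence[Tuple[str, int, str]],
    window_bp: int,
    bin_bp: int,
) -> TssProfile:
    if window_bp <= 0 or bin_bp <= 0 or window_bp % bin_bp:
        raise ValueError("window_bp must be a positive multiple of bin_bp")
    if not anchors:
        raise ValueError("empty anchor selection for profile")
    n_bins = 2 * window_bp // bin_bp
    bins = np.zeros(n_bins, dtype=np.int64)
    anchors_by_chrom: Dict[str, List[Tuple[int, str]]] = {}
    for chrom, pos, strand in anchors:
        anchors_by_chrom.setdefault(chrom, []).append((pos, strand))
    for chrom, items in anchors_by_chrom.items():
        p = breaks.positions(chrom)
        if p.size == 0:
            continue
        for pos, strand in items:
            lo = np.searchsorted(p, pos - window_bp, side="left")
            hi = np.searchsorted(p, pos + window_bp, side="left")
            if hi <= lo:
                continue
            offs = p[lo:hi] - pos
            if strand == "-":
                offs = -offs
            keep = (offs >= -window_bp) & (offs < window_bp)
            idx = (offs[keep] + window_bp) // bin_bp
            np.add.at(bins, idx, 1)
    merged_windows = merge(
        [
            GenomicInterval(chrom, max(0, pos - window_bp), pos + window_bp)
            for chrom, pos, _ in anchors
        ],
        name="profile_windows",
    )
    merged_count = count_overlaps(breaks, merged_windows)
    per_100kb = merged_count / merged_windows.total_bp * 1e5
    per_anchor = int(bins.sum()) / (len(anchors) * 2 * window_bp) * 1e5
    return TssProfile(
        window_bp=window_bp,
        bin_bp=bin_bp,
        bins=bins,
        n_anchors=len(anchors),
        per_100kb=per_100kb,
        per_100kb_per_anchor=per_anchor,
    )


def tss_profile(
    breaks: BreakSet,
    genes: Sequence[GeneRecord],
    window_bp: int = 200,
    bin_bp: int = 20,
) -> TssProfile:
    """Strand-oriented break profile around the TSSs of the supplied genes
    (callers select the gene subset: all, top-K expressed, a DE list...)."""
    anchors = [(g.chrom, g.tss, g.strand) for g in genes]
    return _profile(breaks, anchors, window_bp, bin_bp)


def site_profile(
    breaks: BreakSet,
    sites: Sequence[GenomicInterval],
    window_bp: int = 200,
    bin_bp: int = 20,
) -> TssProfile:
    """Unstranded break profile around binding-site midpoints."""
    anchors = [(s.chrom, s.midpoint, ".") for s in sites]
    return _profile(breaks, anchors, window_bp, bin_bp)


def select_top_expressed(
    genes: Sequence[GeneRecord],
    expression: ExpressionTable,
    sample: str,
    k: int,
) -> List[GeneRecord]:
    """Top-k genes by expression in one sample (ties broken by gene id)."""
    expr = expression.sample_values(sample)
    scored = [(float(expr[g.gene_id]), g) for g in genes if g.gene_id in expr.index]
    scored.sort(key=lambda t: (-t[0], t[1].gene_id))
    return [g for _, g in scored[:k]]


@dataclass(frozen=True)
class GenesWithBreakResult:
    n_genes: int
    n_with_break: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.n_with_break / self.n_genes, 1)


def genes_with_break(breaks: BreakSet, genes: Sequence[GeneRecord]) -> GenesWithBreakResult:
    """How many genes carry >=1 break within their body interval."""
    if not genes:
        raise ValueError("genes_with_break requires at least one gene")
    n_with = 0
    for g in genes:
        p = breaks.positions(g.chrom)
        if p.size and np.searchsorted(p, g.body_start) < np.searchsorted(p, g.body_end):
            n_with += 1
    return GenesWithBreakResult(n_genes=len(genes), n_with_break=n_with)


def fraction_in_regions(breaks: BreakSet, regions: RegionSet) -> float:
    """Fraction of breaks localised inside the region set."""
    if len(breaks) == 0:
        raise ValueError("fraction undefined for an empty break set")
    return count_overlaps(breaks, regions) / len(breaks)


def motif_proximity(
    breaks: BreakSet,
    hits: Sequence[Union[MotifHit, GenomicInterval]],
    distance_bp: int = 50,
) -> float:
    """Fraction of breaks with a motif hit within distance_bp (gap <= d).

    A break at p is counted if some hit [s, e) satisfies
    s - distance_bp <= p < e + distance_bp.
    """
    if len(breaks) == 0:
        raise ValueError("proximity fraction undefined for an empty break set")
    if distance_bp < 0:
        raise ValueError(f"distance_bp must be >= 0, got {distance_bp}")
    widened = merge(
        [
            GenomicInterval(h.chrom, max(0, h.start - distance_bp), h.end + distance_bp)
            for h in hits
        ],
        name="hit_neighbourhoods",
    )
    return count_overlaps(breaks, widened) / len(breaks)


def enrichment_ratio(treated_fraction: float, background_fraction: float) -> float:
    """Fold enrichment of a proximity/density fraction over background."""
    if background_fraction <= 0:
        raise ValueError("background fraction must be positive")
    return treated_fraction / background_fraction
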