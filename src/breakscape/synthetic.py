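"""Synthetic data generator with known ground truth.

Emulates the statistical structure of the pipeline's inputs at desk scale:
a random genome with non-overlapping genes, lognormal expression, an ARE
consensus physically embedded in a controlled fraction of promoters,
breaks drawn from an inhomogeneous Poisson process (background rate with
multiplicative enrichment at the TSS windows of the most-expressed genes
and inside ARE-positive promoters), scored ChIP-seq-like peak sets, and
qPCR dilution series from a log-linear standard curve with Gaussian Ct
noise.  Every enrichment knob is recorded in a truth record so downstream
estimates can be checked against the injected parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_model import BreakSet, GenomicInterval, RegionSet, merge
from .io_formats import ExpressionTable, GeneRecord, MotifPWM
from .motif_scan import MotifHit

# Canonical androgen response element: two 6-bp half-sites with a 3-bp
# spacer, 15 bp total (matching the length of the JASPAR ARE profile).
ARE_CONSENSUS = "AGAACAGCATGTTCT"


def synthetic_are_pfm(name: str = "ARE_synthetic") -> MotifPWM:
    """Synthetic stand-in for an ARE position frequency matrix.

    Built around the canonical 15-bp ARE consensus (AGAACA-nnn-TGTTCT):
    strong counts at the half-sites, softer but still uniquely-argmaxed
    counts at the spacer, so consensus-exact scans (threshold 1.0) match
    the embedded sequence and essentially nothing else.  This is not the
    measured JASPAR profile; it emulates its shape for synthetic runs.
    """
    strong, soft = 17.0, 8.0
    counts = np.ones((4, len(ARE_CONSENSUS)))
    spacer = range(6, 9)
    for j, base in enumerate(ARE_CONSENSUS):
        i = "ACGT".index(base)
        counts[i, j] = soft if j in spacer else strong
    return MotifPWM(name=name, counts=counts)


@dataclass
class QpcrConfig:
    efficiency: float = 0.95
    intercept: float = 36.0          # Ct at one input copy
    noise_sd: float = 0.1            # Gaussian Ct noise per technical replicate
    replicates: int = 3              # technical replicates averaged on the Ct scale
    experiments: int = 3             # independent experiments (sample measurements)
    dilution_points: int = 8         # ten-fold series starting at min_copies
    min_copies: float = 1e2
    cells_per_reaction: float = 100.0
    # TDMD stoichiometry ground truth (copies per cell), at the scale the
    # assay is designed to resolve: sites:miR ratio 4.2 with 2 sites per
    # molecule, 80% silencing efficiency, and 650 miR copies gained per
    # lncRNA copy lost.
    norad_copies_per_cell: float = 2100.0
    mir_copies_per_cell: float = 1000.0
    sites_per_norad: int = 2
    norad_copies_lost: float = 1680.0
    turnover_per_norad: float = 650.0

    @property
    def slope(self) -> float:
        return -1.0 / math.log10(1.0 + self.efficiency)


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 500
    gene_length_range: Tuple[int, int] = (2_000, 20_000)
    expression_lognormal: Tuple[float, float] = (1.0, 1.5)  # (mu, sigma)
    n_expression_samples: int = 20
    frac_are_promoters: float = 0.3
    frac_are_enhancer_peaks: float = 0.3
    promoter_flank_bp: int = 2_000
    background_rate: float = 0.01     # breaks per bp (~100k over 10 Mb)
    rho_tss: float = 10.0             # enrichment at TSS windows of top genes
    rho_are: float = 2.0              # enrichment inside ARE+ promoters
    tss_window_bp: int = 400          # total width of the enriched TSS window
    top_q_genes: int = 100            # genes whose TSSs are enriched
    n_breaks_target: Optional[int] = None
    null_rate_scale: float = 0.1      # endogenous-sample rate relative to background
    n_h3k27ac_peaks: int = 400
    n_ctcf_peaks: int = 600
    peak_width: int = 1_000
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)

    def validate(self) -> None:
        if not (0 <= self.frac_are_promoters <= 1):
            raise ValueError("frac_are_promoters must be in [0, 1]")
        if self.background_rate < 0 or self.rho_tss < 0 or self.rho_are < 0:
            raise ValueError("rates and enrichment factors must be non-negative")
        if self.tss_window_bp % 2:
            raise ValueError("tss_window_bp is a total width and must be even")
        if not (0.5 < self.qpcr.efficiency <= 1.2):
            raise ValueError("qPCR efficiency must lie in (0.5, 1.2]")


@dataclass
class TruthRecord:
    """Everything needed to compute expected enrichments analytically."""

    config: SyntheticConfig
    top_gene_ids: List[str]
    are_positive_gene_ids: List[str]
    are_hit_intervals: List[GenomicInterval]
    tss_enriched_regions: RegionSet
    are_enriched_regions: RegionSet
    expected_break_total: float
    qpcr_slope: float
    qpcr_intercept: float


@dataclass
class SyntheticGenome:
    sequences: Dict[str, str]
    genes: List[GeneRecord]
    expression: ExpressionTable
    are_hits: List[GenomicInterval]
    h3k27ac_peaks: List[GenomicInterval]
    ctcf_peaks: List[GenomicInterval]
    truth: TruthRecord


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length, dtype=np.int8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def _place_genes(
    rng: np.random.Generator, config: SyntheticConfig
) -> List[GeneRecord]:
    """Place non-overlapping gene bodies, gaps distributed multinomially."""
    genes: List[GeneRecord] = []
    chroms = list(config.chrom_lengths)
    total_len = sum(config.chrom_lengths.values())
    # genes per chromosome proportional to length (remainder to the first)
    per_chrom = {c: int(config.n_genes * config.chrom_lengths[c] / total_len) for c in chroms}
    per_chrom[chroms[0]] += config.n_genes - sum(per_chrom.values())
    gi = 0
    for chrom in chroms:
        n = per_chrom[chrom]
        if n == 0:
            continue
        L = config.chrom_lengths[chrom]
        lengths = rng.integers(
            config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
        )
        slack = L - int(lengths.sum())
        if slack < n + 1:
            raise ValueError(
                f"cannot place {n} genes on {chrom} ({L} bp) without overlap; "
                "reduce n_genes or gene lengths"
            )
        gaps = rng.multinomial(slack - (n + 1), np.full(n + 1, 1.0 / (n + 1))) + 1
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start = pos
            end = start + int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(f"gene{gi:04d}", chrom, strand, start, end))
            gi += 1
            pos = end
    return genes


def _draw_expression(
    rng: np.random.Generator, genes: Sequence[GeneRecord], config: SyntheticConfig
) -> ExpressionTable:
    mu, sigma = config.expression_lognormal
    n_g, n_s = len(genes), config.n_expression_samples
    base = rng.lognormal(mean=mu, sigma=sigma, size=n_g)
    # per-sample lognormal jitter around each gene's base level keeps genes
    # rankable in every sample while giving samples realistic spread
    jitter = rng.lognormal(mean=0.0, sigma=0.4, size=(n_g, n_s))
    values = base[:, None] * jitter
    df = pd.DataFrame(
        values,
        index=[g.gene_id for g in genes],
        columns=[f"sample{j:02d}" for j in range(n_s)],
    )
    return ExpressionTable(df)


def generate_genome(config: SyntheticConfig, rng: Optional[np.random.Generator] = None) -> SyntheticGenome:
    """Genome sequence, genes, expression, embedded AREs, peaks and truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequences = {c: _random_sequence(rng, L) for c, L in config.chrom_lengths.items()}
    genes = _place_genes(rng, config)
    expression = _draw_expression(rng, genes, config)

    # embed the ARE consensus inside a controlled fraction of promoters
    n_are = int(round(config.frac_are_promoters * len(genes)))
    are_idx = rng.choice(len(genes), size=n_are, replace=False) if n_are else np.array([], int)
    are_hits: List[GenomicInterval] = []
    are_gene_ids: List[str] = []
    L_are = len(ARE_CONSENSUS)
    seq_arrays = {c: bytearray(s, "ascii") for c, s in sequences.items()}
    for i in sorted(int(j) for j in are_idx):
        g = genes[i]
        chrom_len = config.chrom_lengths[g.chrom]
        lo = max(0, g.tss - config.promoter_flank_bp)
        hi = min(chrom_len, g.tss + config.promoter_flank_bp) - L_are
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        seq_arrays[g.chrom][pos : pos + L_are] = ARE_CONSENSUS.encode("ascii")
        are_hits.append(GenomicInterval(g.chrom, pos, pos + L_are))
        are_gene_ids.append(g.gene_id)
    h3k27ac = _random_peaks(rng, config, config.n_h3k27ac_peaks)
    ctcf = _random_peaks(rng, config, config.n_ctcf_peaks)

    # embed AREs at the centres of a fraction of TSS-distal H3K27ac peaks so
    # the ARE+/ARE- enhancer partition is populated; these carry no break
    # enrichment (only ARE+ promoters do)
    tss_list = [(g.chrom, g.tss) for g in genes]
    distal = [
        k
        for k, p in enumerate(h3k27ac)
        if _is_distal(p, tss_list, config.promoter_flank_bp)
    ]
    n_enh_are = int(round(config.frac_are_enhancer_peaks * len(distal)))
    if n_enh_are:
        chosen = rng.choice(len(distal), size=n_enh_are, replace=False)
        for k in sorted(int(distal[int(j)]) for j in chosen):
            p = h3k27ac[k]
            pos = p.midpoint - L_are // 2
            if pos < 0 or pos + L_are > config.chrom_lengths[p.chrom]:
                continue
            seq_arrays[p.chrom][pos : pos + L_are] = ARE_CONSENSUS.encode("ascii")
            are_hits.append(GenomicInterval(p.chrom, pos, pos + L_are))
    sequences = {c: bytes(a).decode("ascii") for c, a in seq_arrays.items()}

    # ground-truth enrichment geometry
    ref_sample = expression.samples[0]
    expr = expression.sample_values(ref_sample)
    order = sorted(genes, key=lambda g: (-float(expr[g.gene_id]), g.gene_id))
    top = order[: config.top_q_genes]
    half_w = config.tss_window_bp // 2
    tss_regions = merge(
        [
            GenomicInterval(
                g.chrom,
                max(0, g.tss - half_w),
                min(config.chrom_lengths[g.chrom], g.tss + half_w),
            )
            for g in top
        ],
        name="tss_enriched",
    )
    by_id = {g.gene_id: g for g in genes}
    are_regions = merge(
        [
            GenomicInterval(
                by_id[gid].chrom,
                max(0, by_id[gid].tss - config.promoter_flank_bp),
                min(
                    config.chrom_lengths[by_id[gid].chrom],
                    by_id[gid].tss + config.promoter_flank_bp,
                ),
            )
            for gid in are_gene_ids
        ],
        name="are_enriched",
    ) if are_gene_ids else RegionSet("are_enriched", {})

    truth = TruthRecord(
        config=config,
        top_gene_ids=[g.gene_id for g in top],
        are_positive_gene_ids=are_gene_ids,
        are_hit_intervals=are_hits,
        tss_enriched_regions=tss_regions,
        are_enriched_regions=are_regions,
        expected_break_total=_expected_total(config, tss_regions, are_regions),
        qpcr_slope=config.qpcr.slope,
        qpcr_intercept=config.qpcr.intercept,
    )
    return SyntheticGenome(
        sequences=sequences,
        genes=genes,
        expression=expression,
        are_hits=are_hits,
        h3k27ac_peaks=h3k27ac,
        ctcf_peaks=ctcf,
        truth=truth,
    )


def _is_distal(
    peak: GenomicInterval, tss_list: Sequence[Tuple[str, int]], min_dist: int
) -> bool:
    for chrom, t in tss_list:
        if chrom == peak.chrom and peak.start - min_dist <= t <= peak.end - 1 + min_dist:
            return False
    return True


def _random_peaks(
    rng: np.random.Generator, config: SyntheticConfig, n: int
) -> List[GenomicInterval]:
    peaks: List[GenomicInterval] = []
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    picks = rng.choice(len(chroms), size=n, p=probs)
    for k in range(n):
        chrom = chroms[int(picks[k])]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - config.peak_width))
        score = float(rng.lognormal(mean=3.0, sigma=1.0))
        peaks.append(GenomicInterval(chrom, start, start + config.peak_width, score=score))
    return peaks


def _rate_segments(
    config: SyntheticConfig,
    chrom: str,
    tss_regions: RegionSet,
    are_regions: RegionSet,
    base_rate: float,
    enriched: bool,
) -> Tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant per-base rate as (boundaries, rates) arrays."""
    L = config.chrom_lengths[chrom]
    cuts = {0, L}
    factors: List[Tuple[int, int, float]] = []
    if enriched:
        for regions, rho in (
            (tss_regions, config.rho_tss),
            (are_regions, config.rho_are),
        ):
            s, e = regions.bounds(chrom)
            for a, b in zip(s, e):
                cuts.add(int(a))
                cuts.add(int(b))
                factors.append((int(a), int(b), rho))
    bounds = np.array(sorted(c for c in cuts if 0 <= c <= L), dtype=np.int64)
    rates = np.full(bounds.size - 1, base_rate, dtype=float)
    mids = (bounds[:-1] + bounds[1:]) / 2.0
    for a, b, rho in factors:
        rates[(mids >= a) & (mids < b)] *= rho
    return bounds, rates


def _expected_total(
    config: SyntheticConfig, tss_regions: RegionSet, are_regions: RegionSet
) -> float:
    total = 0.0
    for chrom in config.chrom_lengths:
        bounds, rates = _rate_segments(
            config, chrom, tss_regions, are_regions, config.background_rate, True
        )
        total += float((rates * np.diff(bounds)).sum())
    return total


def generate_breaks(
    config: SyntheticConfig,
    genome: SyntheticGenome,
    rng: np.random.Generator,
    sample: str = "treated",
    enriched: bool = True,
    rate_scale: float = 1.0,
) -> BreakSet:
    """Inhomogeneous Poisson break draw over the truth's rate landscape.

    Per segment of constant rate, the count is Poisson(rate * length) and
    positions are uniform within the segment — an exact draw from the
    piecewise-constant process.  ``enriched=False`` gives the homogeneous
    null (an endogenous-breakage sample when combined with rate_scale < 1).
    """
    base = config.background_rate * rate_scale
    if config.n_breaks_target is not None and enriched:
        base *= config.n_breaks_target / max(genome.truth.expected_break_total, 1e-12)
    positions: Dict[str, np.ndarray] = {}
    for chrom in config.chrom_lengths:
        bounds, rates = _rate_segments(
            config,
            chrom,
            genome.truth.tss_enriched_regions,
            genome.truth.are_enriched_regions,
            base,
            enriched,
        )
        seg_len = np.diff(bounds)
        counts = rng.poisson(rates * seg_len)
        chunks = [
            rng.integers(bounds[i], bounds[i + 1], size=int(counts[i]))
            for i in range(len(counts))
            if counts[i] > 0
        ]
        if chunks:
            positions[chrom] = np.sort(np.concatenate(chunks))
    return BreakSet(sample, positions)


def generate_ct_series(
    config: SyntheticConfig, rng: np.random.Generator, assay: str = "target"
) -> pd.DataFrame:
    """Ten-fold dilution series: true copies and Ct per point, each Ct the
    mean of the configured technical replicates."""
    q = config.qpcr
    copies = q.min_copies * 10.0 ** np.arange(q.dilution_points)
    ct = q.intercept + q.slope * np.log10(copies)
    if q.noise_sd > 0:
        ct = ct + rng.normal(
            0.0, q.noise_sd, size=(ct.size, max(1, q.replicates))
        ).mean(axis=1)
    return pd.DataFrame({"assay": assay, "copies": copies, "ct": ct})


def ct_for_copies(config: SyntheticConfig, copies_per_reaction: float,
                  rng: Optional[np.random.Generator] = None) -> float:
    """Ct reading for a known per-reaction copy number: the mean over the
    configured independent experiments, each in technical replicate, with
    Gaussian Ct noise per reading."""
    q = config.qpcr
    ct = q.intercept + q.slope * math.log10(copies_per_reaction)
    n = max(1, q.replicates) * max(1, q.experiments)
    if rng is not None and q.noise_sd > 0:
        ct += float(rng.normal(0.0, q.noise_sd, size=n).mean())
    return ct


def generate_stoichiometry_cts(
    config: SyntheticConfig, rng: np.random.Generator
) -> Dict[str, float]:
    """Ct readings for the four absolute-quantification measurements."""
    q = config.qpcr
    cells = q.cells_per_reaction
    norad_silenced = q.norad_copies_per_cell - q.norad_copies_lost
    mir_silenced = q.mir_copies_per_cell + q.turnover_per_norad * q.norad_copies_lost
    return {
        "norad_unperturbed": ct_for_copies(config, q.norad_copies_per_cell * cells, rng),
        "mir_unperturbed": ct_for_copies(config, q.mir_copies_per_cell * cells, rng),
        "norad_silenced": ct_for_copies(config, norad_silenced * cells, rng),
        "mir_silenced": ct_for_copies(config, mir_silenced * cells, rng),
    }
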