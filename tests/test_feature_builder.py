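"""Promoter/enhancer/insulator construction and the ARE partition."""

import numpy as np
import pandas as pd
import pytest

from breakscape.feature_builder import (
    define_enhancers,
    define_insulators,
    define_promoters,
    partition_by_are,
)
from breakscape.genome_model import GenomicInterval, merge
from breakscape.io_formats import ExpressionTable, GeneRecord

from conftest import random_regions


def expr_table(values):
    return ExpressionTable(
        pd.DataFrame({"ref": values.values()}, index=list(values.keys())).astype(float)
    )


class TestDefinePromoters:
    def test_flank_window(self):
        genes = [GeneRecord("g", "chr1", "+", 10_000, 20_000)]
        rs = define_promoters(genes, expr_table({"g": 5.0}), "ref")
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(8_000, 12_000)]
        assert rs.total_bp == 4_000

    def test_below_threshold_excluded(self):
        genes = [GeneRecord("g", "chr1", "+", 10_000, 20_000)]
        with pytest.raises(ValueError, match="threshold"):
            define_promoters(genes, expr_table({"g": 0.5}), "ref")

    def test_close_tss_merge(self):
        genes = [
            GeneRecord("g1", "chr1", "+", 10_000, 12_000),
            GeneRecord("g2", "chr1", "+", 13_000, 16_000),
        ]
        rs = define_promoters(genes, expr_table({"g1": 2.0, "g2": 2.0}), "ref")
        assert rs.total_bp == 7_000
        assert rs.n_intervals == 1
        # brute-force base membership
        cov = np.zeros(20_000, dtype=bool)
        cov[8_000:12_000] = True
        cov[11_000:15_000] = True
        assert rs.total_bp == int(cov.sum())

    def test_minus_strand_tss(self):
        genes = [GeneRecord("g", "chr1", "-", 10_000, 20_000)]
        rs = define_promoters(genes, expr_table({"g": 2.0}), "ref")
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(17_999, 21_999)]


class TestDefineEnhancers:
    def test_filter_then_rank(self):
        # one proximal peak must be removed before the top-3 ranking
        tss = [("chr1", 50_000)]
        peaks = [
            GenomicInterval("chr1", 49_500, 50_500, score=100),  # proximal
            GenomicInterval("chr1", 10_000, 11_000, score=9),
            GenomicInterval("chr1", 20_000, 21_000, score=8),
            GenomicInterval("chr1", 30_000, 31_000, score=7),
            GenomicInterval("chr1", 40_000, 41_000, score=6),
        ]
        rs = define_enhancers(peaks, tss, top_n=3)
        got = [(iv.start, iv.end) for iv in rs.intervals()]
        assert got == [(10_000, 11_000), (20_000, 21_000), (30_000, 31_000)]

    def test_all_proximal_gives_empty(self):
        tss = [("chr1", 5_000)]
        peaks = [GenomicInterval("chr1", 4_000, 6_000, score=1)]
        rs = define_enhancers(peaks, tss, top_n=5)
        assert rs.total_bp == 0

    def test_boundary_distance_is_strict(self):
        # peak end 1_999 inclusive edge at 1_999; TSS 4_000 gives gap 2_001 > 2_000
        tss = [("chr1", 4_000)]
        distal = GenomicInterval("chr1", 1_000, 2_000, score=1)
        assert define_enhancers([distal], tss, top_n=1).total_bp == 1_000
        # edge exactly 2_000 away is *not* greater than 2 kb -> excluded
        boundary = GenomicInterval("chr1", 1_000, 2_001, score=1)
        assert define_enhancers([boundary], tss, top_n=1).total_bp == 0

    def test_score_ties_broken_by_position(self):
        tss = []
        peaks = [
            GenomicInterval("chr2", 100, 200, score=5),
            GenomicInterval("chr1", 500, 600, score=5),
            GenomicInterval("chr1", 100, 200, score=5),
        ]
        rs = define_enhancers(peaks, tss, top_n=2)
        got = [(iv.chrom, iv.start) for iv in rs.intervals()]
        assert got == [("chr1", 100), ("chr1", 500)]

    def test_output_never_near_tss(self, rng):
        tss = [("chr1", int(t)) for t in rng.integers(0, 100_000, 20)]
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 500, score=float(sc))
            for s, sc in zip(rng.integers(0, 99_500, 100), rng.uniform(0, 10, 100))
        ]
        rs = define_enhancers(peaks, tss, top_n=50)
        for iv in rs.intervals():
            for _, t in tss:
                assert not (iv.start - 2_000 <= t <= iv.end - 1 + 2_000)


class TestDefineInsulators:
    def test_peak_inside_promoter_excluded(self):
        promoters = merge([GenomicInterval("chr1", 0, 10_000)])
        enhancers = merge([])
        peak = GenomicInterval("chr1", 5_000, 5_500, score=1)
        assert define_insulators([peak], promoters, enhancers).total_bp == 0

    def test_abutting_peak_retained(self):
        promoters = merge([GenomicInterval("chr1", 0, 10_000)])
        enhancers = merge([])
        peak = GenomicInterval("chr1", 10_000, 10_500, score=1)
        rs = define_insulators([peak], promoters, enhancers)
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(10_000, 10_500)]

    def test_matches_pairwise_oracle(self, rng):
        promoters = random_regions(rng, 10, span=50_000)
        enhancers = random_regions(rng, 10, span=50_000)
        peaks = [
            GenomicInterval(
                ("chr1", "chr2")[int(rng.integers(2))], int(s), int(s) + 300,
                score=float(rng.uniform()),
            )
            for s in rng.integers(0, 50_000, 20)
        ]
        rs = define_insulators(peaks, promoters, enhancers, top_n=20)
        blocked = list(promoters.intervals()) + list(enhancers.intervals())
        expected = [
            p
            for p in peaks
            if not any(
                b.chrom == p.chrom and b.start < p.end and b.end > p.start
                for b in blocked
            )
        ]
        assert rs.total_bp == merge(expected).total_bp


class TestPartitionByAre:
    def test_hit_assigns_single_region(self):
        regions = merge(
            [GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 5_000, 6_000)]
        )
        hits = [GenomicInterval("chr1", 100, 115)]
        pos, neg = partition_by_are(regions, hits)
        assert pos.n_intervals == 1 and neg.n_intervals == 1
        assert pos.total_bp + neg.total_bp == regions.total_bp

    def test_no_hits_all_negative(self):
        regions = merge([GenomicInterval("chr1", 0, 1_000)])
        pos, neg = partition_by_are(regions, [])
        assert pos.total_bp == 0 and neg.total_bp == regions.total_bp

    def test_straddling_hit_follows_start(self):
        regions = merge(
            [GenomicInterval("chr1", 0, 1_000), GenomicInterval("chr1", 1_005, 2_000)]
        )
        # hit starts in region 1 but extends past its end
        hits = [GenomicInterval("chr1", 995, 1_010)]
        pos, neg = partition_by_are(regions, hits)
        assert [(iv.start, iv.end) for iv in pos.intervals()] == [(0, 1_000)]

    def test_partition_exact_on_random_regions(self, rng):
        for _ in range(10):
            regions = random_regions(rng, 40)
            hits = [
                GenomicInterval("chr1", int(s), int(s) + 15)
                for s in rng.integers(0, 100_000, 25)
            ]
            pos, neg = partition_by_are(regions, hits)
            assert pos.total_bp + neg.total_bp == regions.total_bp
            # disjoint: no base in both
            for chrom in regions.chroms:
                ps, pe = pos.bounds(chrom)
                for a, b in zip(ps, pe):
                    assert not neg.contains(chrom, np.arange(a, b)).any()
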