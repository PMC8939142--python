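"""Break enrichment statistics against brute-force and simulation oracles."""

import numpy as np
import pytest

from breakscape.break_enrichment import (
    break_density,
    enrichment_ratio,
    four_set_density,
    fraction_in_regions,
    genes_with_break,
    motif_proximity,
    sample_overlap_fraction,
    site_profile,
    tss_profile,
)
from breakscape.feature_builder import FeatureClasses, partition_by_are
from breakscape.genome_model import (
    BreakSet,
    GenomicInterval,
    count_overlaps,
    merge,
    merge_region_sets,
)
from breakscape.io_formats import GeneRecord

from conftest import random_breaks, random_regions


def brute_overlap_fraction(query, target, window):
    half = window // 2
    n_hit = 0
    for p in query.points():
        t = target.positions(p.chrom)
        lo, hi = (p.pos, p.pos + 1) if window == 0 else (p.pos - half, p.pos + half)
        if any(lo <= x < hi for x in t):
            n_hit += 1
    return n_hit / len(query)


class TestSampleOverlapFraction:
    def test_window_contains_target(self):
        q = BreakSet("q", {"chr1": [100]})
        t = BreakSet("t", {"chr1": [103]})
        assert sample_overlap_fraction(q, t, 8) == 1.0
        assert sample_overlap_fraction(q, t, 0) == 0.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            sample_overlap_fraction(BreakSet("q", {}), BreakSet("t", {"chr1": [1]}), 8)

    def test_brute_force_and_monotone(self, rng):
        for _ in range(10):
            q = random_breaks(rng, 200, span=20_000, sample="q")
            t = random_breaks(rng, 200, span=20_000, sample="t")
            if len(q) == 0:
                continue
            fractions = [sample_overlap_fraction(q, t, w) for w in (0, 8, 100)]
            assert fractions == sorted(fractions)
            for w, f in zip((0, 8, 100), fractions):
                assert f == pytest.approx(brute_overlap_fraction(q, t, w))


class TestBreakDensity:
    def test_forced_arithmetic(self):
        regions = merge([GenomicInterval("chr1", 0, 3_000)])
        breaks = BreakSet("s", {"chr1": [10, 20, 30, 40, 50, 60]})
        d = break_density(breaks, regions)
        assert d.density_per_kb == 2.0
        assert (d.break_count, d.total_bp) == (6, 3_000)

    def test_zero_breaks(self):
        regions = merge([GenomicInterval("chr1", 0, 1_000)])
        assert break_density(BreakSet("s", {}), regions).density_per_kb == 0.0

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            break_density(BreakSet("s", {"chr1": [1]}), merge([]))

    def test_invariant_to_region_splitting(self):
        breaks = BreakSet("s", {"chr1": list(range(0, 1_000, 7))})
        joined = merge([GenomicInterval("chr1", 0, 1_000)])
        # abutting pieces merge back to the identical region set
        split = merge(
            [GenomicInterval("chr1", 0, 400), GenomicInterval("chr1", 400, 1_000)]
        )
        assert break_density(breaks, joined) == break_density(breaks, split)


class TestFourSetDensity:
    def test_counts_sum_to_union(self, rng):
        promoters = random_regions(rng, 30, span=60_000)
        enhancers = random_regions(rng, 30, span=60_000).rename("enhancers")
        # enhancers must not overlap promoters for the audit to be exact
        from breakscape.genome_model import subtract

        enhancers = subtract(enhancers, promoters, name="enhancers")
        hits = [GenomicInterval("chr1", int(s), int(s) + 15)
                for s in rng.integers(0, 60_000, 15)]
        pp, pn = partition_by_are(promoters, hits)
        ep, en = partition_by_are(enhancers, hits)
        feats = FeatureClasses(promoters, enhancers, merge([]), pp, pn, ep, en)
        breaks = random_breaks(rng, 2_000, span=60_000)
        dens = four_set_density(breaks, feats)
        union = merge_region_sets(promoters, enhancers)
        assert sum(d.break_count for d in dens.values()) == count_overlaps(breaks, union)


class TestTssProfile:
    def genes(self):
        return [
            GeneRecord("g1", "chr1", "+", 10_000, 20_000),
            GeneRecord("g2", "chr1", "-", 40_000, 50_000),
        ]

    def test_zero_breaks_zero_profile(self):
        prof = tss_profile(BreakSet("s", {}), self.genes())
        assert prof.total_in_bins == 0
        assert prof.per_100kb == 0.0

    def test_empty_gene_selection_rejected(self):
        with pytest.raises(ValueError):
            tss_profile(BreakSet("s", {}), [])

    def test_strand_orientation_mirrors_profile(self):
        # a break 60 bp downstream of each TSS must land in the same bin
        breaks = BreakSet("s", {"chr1": [10_060, 49_939]})  # g2 TSS at 49_999, upstream=+
        prof = tss_profile(breaks, self.genes(), window_bp=200, bin_bp=20)
        centre = 200 // 20  # bin index of offset 0
        assert prof.bins[centre + 3] == 2

    def test_flat_profile_under_uniform_breaks(self, rng):
        genes = [
            GeneRecord(f"g{i}", "chr1", "+", int(t), int(t) + 5_000)
            for i, t in enumerate(range(10_000, 400_000, 10_000))
        ]
        rate = 0.02
        n = int(500_000 * rate)
        breaks = BreakSet("s", {"chr1": rng.integers(0, 500_000, n)})
        prof = tss_profile(breaks, genes, window_bp=200, bin_bp=20)
        mean = rate * 20 * len(genes)
        assert (np.abs(prof.bins - mean) <= 4 * np.sqrt(mean) + 1e-9).all()

    def test_single_site_midpoint_break(self):
        sites = [GenomicInterval("chr1", 1_000, 1_100)]
        breaks = BreakSet("s", {"chr1": [1_050]})
        prof = site_profile(breaks, sites, window_bp=100, bin_bp=10)
        assert prof.bins[prof.bins.size // 2] == 1
        assert prof.total_in_bins == 1


class TestGenesWithBreak:
    def test_headline_fixture(self):
        # 18,958 gene bodies; breaks placed in the first 17,222 of them
        genes = [
            GeneRecord(f"g{i}", "chr1", "+", i * 100, i * 100 + 50)
            for i in range(18_958)
        ]
        breaks = BreakSet("s", {"chr1": [i * 100 + 10 for i in range(17_222)]})
        res = genes_with_break(breaks, genes)
        assert (res.n_genes, res.n_with_break) == (18_958, 17_222)
        assert res.percent == 90.8

    def test_extremes(self):
        genes = [GeneRecord(f"g{i}", "chr1", "+", i * 100, i * 100 + 50) for i in range(3)]
        assert genes_with_break(BreakSet("s", {}), genes).percent == 0.0
        allb = BreakSet("s", {"chr1": [10, 110, 210]})
        assert genes_with_break(allb, genes).percent == 100.0

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            genes_with_break(BreakSet("s", {}), [])


class TestFractionInRegions:
    def test_extremes(self):
        regions = merge([GenomicInterval("chr1", 0, 100)])
        inside = BreakSet("s", {"chr1": [1, 2, 3]})
        assert fraction_in_regions(inside, regions) == 1.0
        assert fraction_in_regions(inside, merge([])) == 0.0
        with pytest.raises(ValueError):
            fraction_in_regions(BreakSet("s", {}), regions)

    def test_brute_force(self, rng):
        breaks = random_breaks(rng, 300)
        regions = random_regions(rng, 40)
        ivals = [(iv.chrom, iv.start, iv.end) for iv in regions.intervals()]
        expected = sum(
            1 for p in breaks.points()
            if any(c == p.chrom and s <= p.pos < e for c, s, e in ivals)
        ) / len(breaks)
        assert fraction_in_regions(breaks, regions) == pytest.approx(expected)


class TestMotifProximity:
    def test_gap_rule(self):
        breaks = BreakSet("s", {"chr1": [100]})
        hits = [GenomicInterval("chr1", 140, 155)]
        assert motif_proximity(breaks, hits, 50) == 1.0   # gap 40
        assert motif_proximity(breaks, hits, 30) == 0.0   # gap 40 > 30

    def test_break_inside_hit_counts_at_distance_zero(self):
        breaks = BreakSet("s", {"chr1": [145]})
        hits = [GenomicInterval("chr1", 140, 155)]
        assert motif_proximity(breaks, hits, 0) == 1.0

    def test_enrichment_ratio_of_printed_fractions(self):
        assert enrichment_ratio(0.432, 0.345) == pytest.approx(1.25, abs=0.005)
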