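"""Interval algebra: extension, merging and overlap counting against
brute-force per-base oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breakscape.genome_model import (
    BreakSet,
    GenomicInterval,
    count_overlaps,
    extend_breaks,
    merge,
    subtract,
)

from conftest import random_breaks, random_regions


def coverage_array(region_set, chrom, span):
    """Brute-force boolean per-base coverage."""
    cov = np.zeros(span, dtype=bool)
    for iv in region_set.intervals():
        if iv.chrom == chrom:
            cov[iv.start : min(iv.end, span)] = True
    return cov


class TestGenomicInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 99)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_width(self):
        assert GenomicInterval("chr1", 10, 25).width == 15


class TestExtendBreaks:
    @pytest.mark.parametrize(
        "pos,window,expected",
        [
            (100, 8, (96, 104)),   # centred total-width window
            (2, 8, (0, 6)),        # left-clamped at the chromosome origin
            (100, 0, (100, 101)),  # window 0 keeps the single base
        ],
    )
    def test_single_break_window(self, pos, window, expected):
        bs = BreakSet("s", {"chr1": [pos]})
        ivals = list(extend_breaks(bs, window).intervals())
        assert [(iv.start, iv.end) for iv in ivals] == [expected]

    def test_nearby_breaks_merge(self):
        bs = BreakSet("s", {"chr1": [100, 103]})
        rs = extend_breaks(bs, 8)
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(96, 107)]
        # brute-force per-base membership: bases covered by either window
        cov = coverage_array(rs, "chr1", 200)
        expected = np.zeros(200, dtype=bool)
        for p in (100, 103):
            expected[p - 4 : p + 4] = True
        assert (cov == expected).all()

    def test_symmetric_flag_adds_right_base(self):
        bs = BreakSet("s", {"chr1": [100]})
        rs = extend_breaks(bs, 8, symmetric=True)
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(96, 105)]

    @pytest.mark.parametrize("window", [-2, 3])
    def test_rejects_bad_window(self, window):
        bs = BreakSet("s", {"chr1": [100]})
        with pytest.raises(ValueError):
            extend_breaks(bs, window)

    def test_clamped_at_chromosome_length(self):
        bs = BreakSet("s", {"chr1": [99]})
        rs = extend_breaks(bs, 8, chrom_lengths={"chr1": 100})
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(95, 100)]


class TestMerge:
    def test_overlapping_pair(self):
        rs = merge([GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 15)])
        assert [(iv.start, iv.end) for iv in rs.intervals()] == [(0, 15)]
        assert rs.total_bp == 15

    def test_empty(self):
        rs = merge([])
        assert rs.total_bp == 0
        assert list(rs.intervals()) == []

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 60)), max_size=100),
           st.randoms(use_true_random=False))
    def test_merge_matches_base_membership_oracle(self, pairs, rnd):
        ivals = [GenomicInterval("chr1", s, s + w) for s, w in pairs]
        rnd.shuffle(ivals)
        rs = merge(ivals)
        expected = np.zeros(600, dtype=bool)
        for s, w in pairs:
            expected[s : s + w] = True
        assert (coverage_array(rs, "chr1", 600) == expected).all()
        assert rs.total_bp == int(expected.sum())

    def test_idempotent_and_order_invariant(self, rng):
        regions = random_regions(rng, 50)
        again = merge(list(regions.intervals()))
        assert [(iv.chrom, iv.start, iv.end) for iv in again.intervals()] == [
            (iv.chrom, iv.start, iv.end) for iv in regions.intervals()
        ]
        assert again.total_bp == regions.total_bp


class TestCountOverlaps:
    def test_examples(self):
        regions = merge([GenomicInterval("chr1", 0, 10)])
        assert count_overlaps(BreakSet("s", {"chr1": [5, 50]}), regions) == 1
        assert count_overlaps(BreakSet("s", {}), regions) == 0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(20):
            breaks = random_breaks(rng, 500)
            regions = random_regions(rng, 50)
            ivals = [(iv.chrom, iv.start, iv.end) for iv in regions.intervals()]
            expected = sum(
                1
                for p in breaks.points()
                if any(c == p.chrom and s <= p.pos < e for c, s, e in ivals)
            )
            assert count_overlaps(breaks, regions) == expected

    def test_window_zero_extension_is_point_membership(self, rng):
        breaks = random_breaks(rng, 200)
        regions = random_regions(rng, 30)
        extended = extend_breaks(breaks, 0)
        # the covered bases of the window-0 extension are exactly the distinct
        # break positions, so base counting equals deduplicated point counting
        covered = 0
        for chrom in extended.chroms:
            s, e = extended.bounds(chrom)
            covered += int(
                sum(regions.contains(chrom, np.arange(a, b)).sum() for a, b in zip(s, e))
            )
        assert covered == count_overlaps(breaks.deduplicate(), regions)


class TestSubtract:
    def test_matches_base_oracle(self, rng):
        a = random_regions(rng, 40, span=5_000)
        b = random_regions(rng, 40, span=5_000)
        diff = subtract(a, b)
        for chrom in ("chr1", "chr2"):
            expected = coverage_array(a, chrom, 8_000) & ~coverage_array(b, chrom, 8_000)
            assert (coverage_array(diff, chrom, 8_000) == expected).all()
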