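"""Core genomic coordinate model: points, break sets and merged region sets.

All coordinates are 0-based, half-open (BED convention).  A double-strand
break (DSB) is a single-base genomic point; region sets are kept merged and
sorted so that membership queries are O(log n) searchsorted lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}; expected one of {STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class BreakPoint:
    """A single-nucleotide DSB coordinate; equivalent to [pos, pos+1)."""

    chrom: str
    pos: int
    sample: str = ""

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"break position must be >= 0, got {self.pos}")

    def as_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


class BreakSet:
    """All DSB coordinates of one sample, stored per chromosome, sorted.

    Duplicate (chrom, pos) records are retained by default; deduplication is
    an explicit toggle because break callers may legitimately report
    recurrent breakage at one base.
    """

    def __init__(
        self,
        sample: str,
        positions: Mapping[str, np.ndarray] | Mapping[str, Sequence[int]],
        deduplicated: bool = False,
    ) -> None:
        self.sample = sample
        self.deduplicated = deduplicated
        self._pos: Dict[str, np.ndarray] = {}
        for chrom, arr in positions.items():
            a = np.asarray(arr, dtype=np.int64)
            if a.size and a.min() < 0:
                raise ValueError(f"negative break position on {chrom}")
            a = np.sort(a)
            if deduplicated:
                a = np.unique(a)
            if a.size:
                self._pos[chrom] = a

    @classmethod
    def from_points(
        cls, points: Iterable[BreakPoint], sample: str, deduplicate: bool = False
    ) -> "BreakSet":
        by_chrom: Dict[str, List[int]] = {}
        for p in points:
            by_chrom.setdefault(p.chrom, []).append(p.pos)
        return cls(sample, by_chrom, deduplicated=deduplicate)

    def deduplicate(self) -> "BreakSet":
        return BreakSet(self.sample, self._pos, deduplicated=True)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._pos)

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    @property
    def n_breaks(self) -> int:
        return int(sum(a.size for a in self._pos.values()))

    def __len__(self) -> int:
        return self.n_breaks

    def points(self) -> Iterator[BreakPoint]:
        for chrom in self.chroms:
            for pos in self._pos[chrom]:
                yield BreakPoint(chrom, int(pos), self.sample)


class RegionSet:
    """A named collection of merged, sorted, pairwise-disjoint intervals."""

    def __init__(self, name: str, ivals: Mapping[str, Tuple[np.ndarray, np.ndarray]]):
        # `ivals` must already be merged/sorted; use `merge` to build safely.
        self.name = name
        self._ivals: Dict[str, Tuple[np.ndarray, np.ndarray]] = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in ivals.items()
            if len(s)
        }

    @property
    def chroms(self) -> List[str]:
        return sorted(self._ivals)

    def bounds(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if chrom in self._ivals:
            return self._ivals[chrom]
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    @property
    def total_bp(self) -> int:
        return int(sum((e - s).sum() for s, e in self._ivals.values()))

    @property
    def n_intervals(self) -> int:
        return int(sum(len(s) for s, _ in self._ivals.values()))

    def intervals(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            s, e = self._ivals[chrom]
            for a, b in zip(s, e):
                yield GenomicInterval(chrom, int(a), int(b))

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean membership of positions in this (merged) region set."""
        starts, ends = self.bounds(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        if starts.size == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] < ends[idx[ok]]
        return hit

    def rename(self, name: str) -> "RegionSet":
        return RegionSet(name, self._ivals)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Merge intervals already sorted by start; abutting intervals coalesce."""
    if starts.size == 0:
        return starts, ends
    out_s = [starts[0]]
    out_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def merge(intervals: Iterable[GenomicInterval], name: str = "") -> RegionSet:
    """Merge arbitrary intervals into a minimal disjoint covering set.

    The result covers exactly the same bases; abutting pieces are joined so
    the representation is canonical (order of input does not matter).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(sorted(pairs), dtype=np.int64)
        merged[chrom] = _merge_sorted(arr[:, 0], arr[:, 1])
    return RegionSet(name, merged)


def merge_region_sets(a: RegionSet, b: RegionSet, name: str = "") -> RegionSet:
    """Union of two merged region sets."""
    return merge(list(a.intervals()) + list(b.intervals()), name=name)


def extend_breaks(
    breaks: BreakSet,
    window_bp: int,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    symmetric: bool = False,
    name: str = "",
) -> RegionSet:
    """Extend single-base breaks to centred windows and merge.

    A break at p becomes [p - w/2, p + w/2) for total window width w > 0
    (so an "8 nt window" covers 4 bases either side of the half-open point);
    w = 0 keeps the point as [p, p+1).  With ``symmetric=True`` the window is
    instead every base q with \\|q - p\\| <= w/2, i.e. [p - w/2, p + w/2 + 1).
    Windows are clamped at 0 and, when chromosome lengths are supplied, at
    the chromosome end.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be non-negative, got {window_bp}")
    if window_bp % 2 != 0:
        raise ValueError(f"window_bp is a total width and must be even, got {window_bp}")
    half = window_bp // 2
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in breaks.chroms:
        pos = breaks.positions(chrom)
        if window_bp == 0:
            s, e = pos, pos + 1
        else:
            s = pos - half
            e = pos + half + (1 if symmetric else 0)
        s = np.maximum(s, 0)
        if chrom_lengths is not None and chrom in chrom_lengths:
            e = np.minimum(e, chrom_lengths[chrom])
        keep = e > s
        out[chrom] = _merge_sorted(s[keep], e[keep])
    return RegionSet(name or f"{breaks.sample}_w{window_bp}", out)


def count_overlaps(breaks: BreakSet, regions: RegionSet) -> int:
    """Number of break records whose position lies inside the region set.

    Each break record is counted at most once; duplicate records each count.
    """
    total = 0
    for chrom in breaks.chroms:
        total += int(regions.contains(chrom, breaks.positions(chrom)).sum())
    return total


def subtract(regions: RegionSet, other: RegionSet, name: str = "") -> RegionSet:
    """Bases of `regions` not covered by `other` (both merged)."""
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in regions.chroms:
        rs, re = regions.bounds(chrom)
        os_, oe = other.bounds(chrom)
        new_s: List[int] = []
        new_e: List[int] = []
        j = 0
        for s, e in zip(rs, re):
            cur = s
            while j < len(os_) and oe[j] <= cur:
                j += 1
            k = j
            while k < len(os_) and os_[k] < e:
                if os_[k] > cur:
                    new_s.append(int(cur))
                    new_e.append(int(os_[k]))
                cur = max(cur, int(oe[k]))
                if cur >= e:
                    break
                k += 1
            if cur < e:
                new_s.append(int(cur))
                new_e.append(int(e))
        out[chrom] = (np.asarray(new_s, dtype=np.int64), np.asarray(new_e, dtype=np.int64))
    return RegionSet(name, out)
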