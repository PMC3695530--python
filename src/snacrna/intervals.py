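"""Genomic interval algebra on a fixed genome layout.

All coordinates are 0-based, half-open (BED native). Wiggle-style 1-based
coordinates are converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")


class CoordinateError(ValueError):
    """An interval falls outside the genome layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths plus the tiling-array geometry.

    Parameters
    ----------
    lengths
        Mapping of chromosome name -> length in bp (insertion order is the
        chromosome order).
    tiling_step
        Distance between consecutive probe starts (bp); whole-genome
        tiling platforms typically tile at 30-bp resolution.
    probe_length
        Length of each tiled probe (bp); 25-mers by Affymetrix convention.
    """

    lengths: dict[str, int]
    tiling_step: int = 30
    probe_length: int = 25

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {n}")
        if self.tiling_step < 1:
            raise ValueError("tiling_step must be >= 1")
        if self.probe_length < 1:
            raise ValueError("probe_length must be >= 1")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def genome_bp(self) -> int:
        return sum(self.lengths.values())

    def probe_starts(self, chrom: str) -> np.ndarray:
        """Starts of all probes fully contained in ``chrom`` on the tiling grid."""
        n = self.lengths[chrom]
        last = n - self.probe_length
        if last < 0:
            return np.empty(0, dtype=np.int64)
        return np.arange(0, last + 1, self.tiling_step, dtype=np.int64)

    def check(self, chrom: str, start: int, end: int) -> None:
        if chrom not in self.lengths:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= self.lengths[chrom]):
            raise CoordinateError(
                f"{chrom}:{start}-{end} outside [0, {self.lengths[chrom]})"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval with an optional strand ('.' = unknown)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class IntervalSet:
    """Disjoint, sorted intervals per chromosome (strand-agnostic).

    Backed by (n, 2) int64 arrays of [start, end) rows. The canonical
    container for the exonic/intronic/intergenic genome partition, repeat
    masks and rRNA indexes.
    """

    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(
        cls, intervals, layout: GenomeLayout | None = None
    ) -> "IntervalSet":
        """Build a merged set from any iterable of GenomicInterval."""
        raw: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            if layout is not None:
                layout.check(iv.chrom, iv.start, iv.end)
            raw.setdefault(iv.chrom, []).append((iv.start, iv.end))
        by_chrom = {}
        for chrom, pairs in raw.items():
            by_chrom[chrom] = _merge_pairs(np.array(pairs, dtype=np.int64))
        return cls(by_chrom)

    def arr(self, chrom: str) -> np.ndarray:
        return self.by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    @property
    def total_bp(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self.by_chrom.values())
        )

    def __len__(self) -> int:
        return sum(len(a) for a in self.by_chrom.values())

    def intersect_bp(self, iv: GenomicInterval) -> int:
        """bp of overlap between ``iv`` and this set (half-open semantics)."""
        a = self.arr(iv.chrom)
        if len(a) == 0:
            return 0
        lo = np.maximum(a[:, 0], iv.start)
        hi = np.minimum(a[:, 1], iv.end)
        return int(np.maximum(hi - lo, 0).sum())

    def overlaps(self, iv: GenomicInterval) -> bool:
        return self.intersect_bp(iv) > 0

    def contains(self, iv: GenomicInterval) -> bool:
        return self.intersect_bp(iv) == len(iv)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self.by_chrom) | set(other.by_chrom):
            both = np.vstack([self.arr(chrom), other.arr(chrom)])
            out[chrom] = _merge_pairs(both)
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom, a in self.by_chrom.items():
            b = other.arr(chrom)
            out[chrom] = _subtract_pairs(a, b)
        return IntervalSet(out)

    def complement(self, layout: GenomeLayout) -> "IntervalSet":
        out = {}
        for chrom, n in layout.lengths.items():
            whole = np.array([[0, n]], dtype=np.int64)
            out[chrom] = _subtract_pairs(whole, self.arr(chrom))
        return IntervalSet(out)

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.by_chrom:
            for s, e in self.by_chrom[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out


def _merge_pairs(pairs: np.ndarray) -> np.ndarray:
    """Merge possibly-overlapping [start, end) rows into disjoint sorted rows.

    Touching intervals (end == next start) are coalesced; half-open overlap
    queries treat them identically either way.
    """
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.int64)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    merged = [list(pairs[0])]
    for s, e in pairs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def _subtract_pairs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a minus b, both disjoint & sorted."""
    if len(a) == 0 or len(b) == 0:
        return a.copy()
    out = []
    for s, e in a:
        cur = s
        sel = b[(b[:, 1] > s) & (b[:, 0] < e)]
        for bs, be in sel:
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(out, dtype=np.int64)


def merge_intervals(
    intervals, layout: GenomeLayout | None = None
) -> list[GenomicInterval]:
    """Merge intervals into a disjoint, sorted, strand-agnostic list.

    Total bp of the result equals the bp of the input union. Chromosome
    order follows the layout when given, else lexicographic.
    """
    iset = IntervalSet.from_intervals(intervals, layout=layout)
    order = layout.chromosomes if layout is not None else sorted(iset.by_chrom)
    out = []
    for chrom in order:
        for s, e in iset.arr(chrom):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def overlap_bp(iv: GenomicInterval, iset: IntervalSet) -> int:
    """bp of intersection between one interval and an interval set."""
    return iset.intersect_bp(iv)
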