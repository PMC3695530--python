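"""Strand-specific read counting, RPKM, transfrag validation and orientation.

Consumes stranded alignments (BED6-style intervals of fixed read length);
alignment itself is upstream. RPKM follows
10^9 * reads_in_region / (region_length * total_mapped), with the
denominator taken as the post-filter retained read count by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationSet
from .intervals import GenomicInterval, IntervalSet
from .transfrags import Transfrag


@dataclass
class ReadSet:
    """Fixed-length stranded reads, sorted per (chromosome, strand).

    ``starts`` maps (chrom, strand) -> sorted int64 start positions;
    ``total_mapped`` is the retained read count used as RPKM denominator.
    """

    sample: str
    read_length: int
    starts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    total_mapped: int = 0

    @classmethod
    def from_intervals(cls, sample: str, read_length: int, intervals) -> "ReadSet":
        raw: dict[tuple[str, str], list[int]] = {}
        n = 0
        for iv in intervals:
            if iv.strand not in ("+", "-"):
                raise ValueError("reads must be stranded")
            raw.setdefault((iv.chrom, iv.strand), []).append(iv.start)
            n += 1
        starts = {k: np.sort(np.array(v, dtype=np.int64)) for k, v in raw.items()}
        return cls(sample, read_length, starts, n)

    def to_intervals(self):
        L = self.read_length
        for (chrom, strand), arr in sorted(self.starts.items()):
            for s in arr:
                yield GenomicInterval(chrom, int(s), int(s) + L, strand)


def filter_reads(
    reads: ReadSet,
    chrm_name: str = "chrM",
    rrna: IntervalSet | None = None,
    repeat_mask: IntervalSet | None = None,
) -> ReadSet:
    """Drop reads on the mitochondrial chromosome or overlapping (>= 1 bp)
    ribosomal intervals or the repeat mask; updates total_mapped."""
    L = reads.read_length
    kept: dict[tuple[str, str], np.ndarray] = {}
    total = 0
    for (chrom, strand), starts in reads.starts.items():
        if chrom == chrm_name:
            continue
        keep = np.ones(len(starts), dtype=bool)
        for mask in (rrna, repeat_mask):
            if mask is None:
                continue
            for ms, me in mask.arr(chrom):
                keep &= ~((starts < me) & (starts + L > ms))
        kept[(chrom, strand)] = starts[keep]
        total += int(keep.sum())
    return ReadSet(reads.sample, L, kept, total)


def count_reads(region: GenomicInterval, reads: ReadSet, mode: str = "both") -> int:
    """Number of reads overlapping ``region`` by >= 1 bp on the selected strand(s)."""
    strands = {"both": ("+", "-"), "plus": ("+",), "minus": ("-",)}[mode]
    L = reads.read_length
    n = 0
    for strand in strands:
        starts = reads.starts.get((region.chrom, strand))
        if starts is None or len(starts) == 0:
            continue
        lo = np.searchsorted(starts, region.start - L + 1, side="left")
        hi = np.searchsorted(starts, region.end, side="left")
        n += int(hi - lo)
    return n


def rpkm(reads_in_region: int, region_length: int, total_mapped: int) -> float:
    """10^9 * reads / (length * total); reads per kilobase per million mapped."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if total_mapped <= 0:
        raise ValueError("rpkm undefined for total_mapped = 0")
    return 1e9 * reads_in_region / (region_length * total_mapped)


@dataclass
class RegionQuant:
    region: GenomicInterval
    reads_plus: int
    reads_minus: int
    rpkm: float
    validated: bool
    inferred_strand: str  # "+", "-", "undetermined"
    orientation_vs_host: str  # "sense", "antisense", "none", "ambiguous"
    host_gene: str | None = None


def validate_transfrag(t: Transfrag, reads: ReadSet) -> bool:
    """Validated iff >= 1 mapped read overlaps the transfrag (either strand)."""
    return count_reads(t.interval, reads, "both") >= 1


def infer_strand(t: Transfrag, reads: ReadSet) -> str:
    """Strict majority vote of overlapping read strands; ties/zero -> undetermined."""
    plus = count_reads(t.interval, reads, "plus")
    minus = count_reads(t.interval, reads, "minus")
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return "undetermined"


def host_gene(t: Transfrag, annotation: AnnotationSet):
    """Gene with maximal bp overlap; (None, ambiguous flag) on tie or no overlap."""
    best, best_bp, tie = None, 0, False
    for g in annotation.genes:
        bp = t.interval.overlap_bp(g.interval)
        if bp > best_bp:
            best, best_bp, tie = g, bp, False
        elif bp == best_bp and bp > 0:
            tie = True
    if best is None:
        return None, False
    return best, tie


def classify_orientation(t: Transfrag, inferred: str, annotation: AnnotationSet) -> tuple[str, str | None]:
    """Sense/antisense of a transfrag relative to its host gene.

    'none' for intergenic transfrags or undetermined strand; 'ambiguous'
    when two genes overlap the transfrag by the same (maximal) bp, in which
    case the host cannot be assigned reliably.
    """
    if inferred == "undetermined":
        return "none", None
    gene, tie = host_gene(t, annotation)
    if gene is None:
        return "none", None
    if tie:
        return "ambiguous", None
    return ("sense" if inferred == gene.strand else "antisense"), gene.gene_id


def quantify_transfrags(
    transfrags: list[Transfrag],
    reads: ReadSet,
    annotation: AnnotationSet | None = None,
) -> list[RegionQuant]:
    """Per-transfrag counts, RPKM, validation, strand and host orientation."""
    out = []
    for t in transfrags:
        plus = count_reads(t.interval, reads, "plus")
        minus = count_reads(t.interval, reads, "minus")
        inferred = infer_strand(t, reads)
        orientation, host = "none", None
        if annotation is not None:
            orientation, host = classify_orientation(t, inferred, annotation)
        out.append(
            RegionQuant(
                region=t.interval,
                reads_plus=plus,
                reads_minus=minus,
                rpkm=rpkm(plus + minus, len(t.interval), reads.total_mapped),
                validated=(plus + minus) >= 1,
                inferred_strand=inferred,
                orientation_vs_host=orientation,
                host_gene=host,
            )
        )
    return out


def read_density_tracks(reads: ReadSet, layout, bin_size: int = 30):
    """Binned per-strand read-start density, {strand: {chrom: (starts, values)}};
    suitable for bedGraph export as a genome-browser track."""
    out = {"+": {}, "-": {}}
    for chrom, n in layout.lengths.items():
        edges = np.arange(0, n + bin_size, bin_size)
        for strand in ("+", "-"):
            starts = reads.starts.get((chrom, strand))
            if starts is None:
                continue
            counts, _ = np.histogram(starts, bins=edges)
            nz = np.flatnonzero(counts)
            out[strand][chrom] = (edges[nz], counts[nz].astype(float))
    return out
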