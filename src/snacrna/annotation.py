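"""Gene models and the derived exonic/intronic/intergenic genome partition."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import GenomeLayout, GenomicInterval, IntervalSet

BIOTYPES = ("coding", "histone_canonical", "histone_variant", "ncRNA")


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene with sorted, non-overlapping exons.

    Canonical replication-dependent histone genes (biotype
    ``histone_canonical``) are intronless and serve as the pipeline's
    positive control for non-polyadenylated transcription.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"gene {self.gene_id}: unknown biotype {self.biotype!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for e in exons:
            if e.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if e.start < self.interval.start or e.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene body")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


@dataclass
class AnnotationSet:
    """Genes plus the strand-agnostic genome partition and repeat mask.

    ``exonic`` is the non-redundant merge of all exons, ``intronic`` is the
    merged gene bodies minus exonic, and ``intergenic`` the complement; the
    three partition the genome exactly (every bp counted once).
    """

    layout: GenomeLayout
    genes: list[GeneModel]
    exonic: IntervalSet
    intronic: IntervalSet
    intergenic: IntervalSet
    repeat_mask: IntervalSet = field(default_factory=IntervalSet)

    def genome_fractions(self) -> dict[str, float]:
        g = self.layout.genome_bp
        return {
            "exonic": self.exonic.total_bp / g,
            "intronic": self.intronic.total_bp / g,
            "intergenic": self.intergenic.total_bp / g,
        }

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def build_genome_partition(
    genes: list[GeneModel],
    layout: GenomeLayout,
    repeat_mask: IntervalSet | None = None,
) -> AnnotationSet:
    """Partition the genome into exonic / intronic / intergenic bp.

    Exon bp shared between isoform-like overlapping genes is counted once
    (non-redundant merge); any bp that is exonic in one gene and intronic in
    another counts as exonic.
    """
    for g in genes:
        layout.check(g.interval.chrom, g.interval.start, g.interval.end)
    exonic = IntervalSet.from_intervals(e for g in genes for e in g.exons)
    bodies = IntervalSet.from_intervals(g.interval for g in genes)
    intronic = bodies.subtract(exonic)
    intergenic = bodies.complement(layout)
    return AnnotationSet(
        layout=layout,
        genes=list(genes),
        exonic=exonic,
        intronic=intronic,
        intergenic=intergenic,
        repeat_mask=repeat_mask if repeat_mask is not None else IntervalSet(),
    )
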