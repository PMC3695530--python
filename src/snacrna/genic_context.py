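"""Genomic-context classification of transfrags and enrichment statistics.

A transfrag is exonic if it touches merged exonic space by >= 1 bp, intronic
if entirely contained in intronic space, and intergenic otherwise. Fold
enrichment normalizes category counts by the category's proportional
representation in the genome; significance uses Fisher's exact test on
observed vs expected counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .annotation import AnnotationSet, GeneModel
from .intervals import GenomicInterval, IntervalSet
from .transfrags import Transfrag

CATEGORIES = ("exonic", "intronic", "intergenic")


@dataclass
class EnrichmentResult:
    category: str
    observed_count: int
    total_count: int
    genome_fraction: float
    fold_enrichment: float
    p_value: float
    p_adjusted: float | None = None


def classify_transfrag(t: Transfrag, annotation: AnnotationSet) -> str:
    """One of exonic / intronic / intergenic (exact partition of transfrags)."""
    iv = t.interval
    if annotation.exonic.overlaps(iv):
        return "exonic"
    if annotation.intronic.contains(iv):
        return "intronic"
    return "intergenic"


def classify_all(transfrags, annotation) -> dict[str, str]:
    """Category per transfrag keyed by 'chrom:start-end'."""
    return {
        f"{t.interval.chrom}:{t.interval.start}-{t.interval.end}": classify_transfrag(
            t, annotation
        )
        for t in transfrags
    }


def compute_enrichment(
    observed_count: int,
    total_count: int,
    genome_fraction: float,
    category: str = "",
) -> EnrichmentResult:
    """Fold enrichment and Fisher exact p for one category.

    fold = (observed/total) / genome_fraction. The 2x2 table contrasts the
    observed in/out split with the expected split under proportional
    placement, expected = round-half-up(total * genome_fraction).
    """
    if total_count <= 0:
        raise ValueError("total_count must be positive")
    if genome_fraction <= 0:
        if observed_count > 0:
            raise ValueError(
                f"category {category!r}: zero genome fraction with observed > 0"
            )
        return EnrichmentResult(category, 0, total_count, 0.0, 0.0, 1.0)
    fold = (observed_count / total_count) / genome_fraction
    expected = int(math.floor(total_count * genome_fraction + 0.5))
    table = [
        [observed_count, total_count - observed_count],
        [expected, total_count - expected],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return EnrichmentResult(category, observed_count, total_count, genome_fraction, fold, p)


def enrichment_report(
    transfrags, annotation: AnnotationSet
) -> list[EnrichmentResult]:
    """Fold enrichment per exonic/intronic/intergenic with BH-adjusted p."""
    labels = [classify_transfrag(t, annotation) for t in transfrags]
    fractions = annotation.genome_fractions()
    total = len(labels)
    results = [
        compute_enrichment(labels.count(cat), total, fractions[cat], cat)
        for cat in CATEGORIES
    ]
    _bh_adjust(results)
    return results


def _bh_adjust(results: list[EnrichmentResult]) -> None:
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_value)
    prev = 1.0
    for rank, i in list(enumerate(order, 1))[::-1]:
        adj = min(prev, results[i].p_value * m / rank)
        results[i].p_adjusted = adj
        prev = adj


def categorize_exons(gene: GeneModel) -> list[str]:
    """Label each exon 5prime / 3prime / single.

    Single-exon genes get 'single'. Otherwise an exon is 5prime when its
    midpoint lies at or upstream (in transcript orientation) of the
    gene-body midpoint, else 3prime; the tie at the midpoint breaks toward
    5prime.
    """
    if gene.single_exon:
        return ["single"]
    gmid = (gene.interval.start + gene.interval.end) / 2
    labels = []
    for exon in gene.exons:
        emid = (exon.start + exon.end) / 2
        if gene.strand == "+":
            labels.append("5prime" if emid <= gmid else "3prime")
        else:
            labels.append("5prime" if emid >= gmid else "3prime")
    return labels


def exon_subpartitions(genes, layout) -> dict[str, IntervalSet]:
    """Merged interval sets for 5prime / 3prime / single exon categories."""
    buckets: dict[str, list[GenomicInterval]] = {
        "5prime_exon": [],
        "3prime_exon": [],
        "single_exon": [],
    }
    for g in genes:
        for exon, lab in zip(g.exons, categorize_exons(g)):
            key = {"5prime": "5prime_exon", "3prime": "3prime_exon", "single": "single_exon"}[lab]
            buckets[key].append(exon)
    return {k: IntervalSet.from_intervals(v) for k, v in buckets.items()}


def exon_bias_enrichment(
    transfrags, genes, layout
) -> list[EnrichmentResult]:
    """Enrichment of transfrag overlap with 5prime/3prime/single exon space.

    A transfrag counts in a category when it overlaps that exon set by
    >= 1 bp (a transfrag may count in more than one category). Categories
    with zero genome fraction and zero observed are skipped.
    """
    subsets = exon_subpartitions(genes, layout)
    genome_bp = layout.genome_bp
    total = len(transfrags)
    results = []
    for cat, iset in subsets.items():
        frac = iset.total_bp / genome_bp
        obs = sum(1 for t in transfrags if iset.overlaps(t.interval))
        if frac == 0 and obs == 0:
            continue
        results.append(compute_enrichment(obs, total, frac, cat))
    _bh_adjust(results)
    return results
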