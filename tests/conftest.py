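import numpy as np
import pytest

from snacrna.annotation import GeneModel, build_genome_partition
from snacrna.intervals import GenomeLayout, GenomicInterval
from snacrna.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture(scope="session")
def toy_annotation(small_layout):
    """Two multi-exon genes (one per strand) and one single-exon gene."""
    genes = [
        GeneModel(
            "gA",
            GenomicInterval("chr1", 1000, 3000, "+"),
            (
                GenomicInterval("chr1", 1000, 1200, "+"),
                GenomicInterval("chr1", 1800, 2000, "+"),
                GenomicInterval("chr1", 2800, 3000, "+"),
            ),
        ),
        GeneModel(
            "gB",
            GenomicInterval("chr1", 5000, 7000, "-"),
            (
                GenomicInterval("chr1", 5000, 5300, "-"),
                GenomicInterval("chr1", 6700, 7000, "-"),
            ),
        ),
        GeneModel(
            "gH",
            GenomicInterval("chr2", 1000, 1500, "+"),
            (GenomicInterval("chr2", 1000, 1500, "+"),),
            biotype="histone_canonical",
        ),
    ]
    return build_genome_partition(genes, small_layout)


@pytest.fixture(scope="session")
def dataset():
    """Default-condition synthetic dataset at reduced sequencing depth
    (array-side stages do not need the full library)."""
    cfg = SyntheticConfig(seed=11, reads_per_sample=300_000)
    return generate_dataset(cfg)


def bitmap_overlap_bp(iv, intervals, genome_len=100_000):
    """Per-base boolean-mask oracle for interval overlap (small genomes)."""
    mask = np.zeros(genome_len, dtype=bool)
    for other in intervals:
        if other.chrom == iv.chrom:
            mask[other.start : other.end] = True
    return int(mask[iv.start : iv.end].sum())
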