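"""Center-aligned ChIP read-density matrices and k-means profile clustering.

Reproduces a seqMiner-style workflow: binned read densities in a fixed
window around region centers, one block of columns per chromatin mark,
k-means clustered (k = 6 by default) with cluster labels renumbered by
descending size, and mean per-cluster profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .intervals import GenomicInterval
from .rnaseq import ReadSet


@dataclass
class EpiProfileMatrix:
    regions: list[GenomicInterval]
    marks: list[str]
    window: int
    bin_size: int
    densities: np.ndarray  # regions x (bins * marks)
    truncated: np.ndarray  # bool per region (window clipped at chrom edge)
    cluster_labels: np.ndarray | None = None
    k: int | None = None

    @property
    def n_bins(self) -> int:
        return self.window // self.bin_size

    def mark_block(self, mark: str) -> np.ndarray:
        i = self.marks.index(mark)
        return self.densities[:, i * self.n_bins : (i + 1) * self.n_bins]


def build_profile_matrix(
    regions: list[GenomicInterval],
    chip_reads: dict[str, ReadSet],
    layout,
    window: int = 10_000,
    bin_size: int = 50,
) -> EpiProfileMatrix:
    """Read-count matrix over [center - window/2, center + window/2) per mark.

    Reads are counted by 5'-end position (one bin per read, no
    double-counting across bins). Windows truncated at chromosome edges are
    zero-padded outside the chromosome and flagged.
    """
    if window % bin_size != 0:
        raise ValueError("window must be an even multiple of bin_size")
    n_bins = window // bin_size
    half = window // 2
    marks = list(chip_reads)
    mat = np.zeros((len(regions), n_bins * len(marks)))
    truncated = np.zeros(len(regions), dtype=bool)
    for ri, region in enumerate(regions):
        center = (region.start + region.end) // 2
        left = center - half
        truncated[ri] = left < 0 or center + half > layout.lengths[region.chrom]
        for mi, mark in enumerate(marks):
            reads = chip_reads[mark]
            for strand in ("+", "-"):
                starts = reads.starts.get((region.chrom, strand))
                if starts is None or len(starts) == 0:
                    continue
                five = starts if strand == "+" else starts + reads.read_length - 1
                five = np.sort(five)
                lo = np.searchsorted(five, left, "left")
                hi = np.searchsorted(five, left + window, "left")
                if hi > lo:
                    bins = (five[lo:hi] - left) // bin_size
                    mat[ri, mi * n_bins : (mi + 1) * n_bins] += np.bincount(
                        bins, minlength=n_bins
                    )
    return EpiProfileMatrix(regions, marks, window, bin_size, mat, truncated)


def cluster_profiles(matrix: EpiProfileMatrix, k: int = 6, seed: int = 0) -> np.ndarray:
    """k-means over profile rows; labels 1..k renumbered by descending size."""
    if len(matrix.regions) < k:
        raise ValueError(f"k={k} exceeds number of regions {len(matrix.regions)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(matrix.densities)
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    labels = remap[raw]
    matrix.cluster_labels = labels
    matrix.k = k
    return labels


def mean_cluster_profiles(
    matrix: EpiProfileMatrix, labels: np.ndarray | None = None
) -> dict[int, dict[str, np.ndarray]]:
    """Arithmetic mean density per cluster, per mark, per bin."""
    if labels is None:
        labels = matrix.cluster_labels
    if labels is None:
        raise ValueError("no cluster labels; run cluster_profiles first")
    out: dict[int, dict[str, np.ndarray]] = {}
    for lab in np.unique(labels):
        rows = matrix.densities[labels == lab]
        out[int(lab)] = {
            mark: rows[
                :, i * matrix.n_bins : (i + 1) * matrix.n_bins
            ].mean(axis=0)
            for i, mark in enumerate(matrix.marks)
        }
    return out
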