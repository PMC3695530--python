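"""snacRNA candidate screen: histone-calibrated RPKM threshold, ORF filter,
conservation resampling significance, homology-record filtering and
differential ranking.

snacRNAs (small non-polyA conserved RNAs) are intronic/intergenic
transfrags whose abundance matches bona fide non-polyadenylated genes
(above the 5th percentile of histone-transfrag RPKM), with low coding
potential (longest ORF <= 100 aa) and significantly elevated conservation
relative to length-matched random intergenic loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, IntervalSet

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------- threshold

def histone_rpkm_threshold(rpkms_by_cell: dict[str, np.ndarray]) -> float:
    """log10-RPKM screen threshold calibrated on histone transfrags.

    Per cell type: 5th percentile of log10(rpkm) over transfrags overlapping
    histone gene exons (zero-RPKM entries excluded); the final threshold is
    the mean across cell types, preserving ~95% histone recall in each.
    """
    per_cell = []
    for cell, arr in rpkms_by_cell.items():
        arr = np.asarray(arr, dtype=float)
        pos = arr[arr > 0]
        if len(pos) == 0:
            raise ValueError(f"no positive histone RPKMs for cell type {cell!r}")
        if len(pos) < len(arr):
            import warnings

            warnings.warn(
                f"{len(arr) - len(pos)} zero-RPKM histone transfrags excluded "
                f"({cell})",
                stacklevel=2,
            )
        per_cell.append(float(np.percentile(np.log10(pos), 5)))
    if not per_cell:
        raise ValueError("no histone transfrags to calibrate on")
    return float(np.mean(per_cell))


# ---------------------------------------------------------------- ORF scan

def _scan_frames(seq: str) -> int:
    best = 0
    n = len(seq)
    for frame in range(3):
        orf_start = None  # codon index of first ATG since last stop/N break
        codon_i = 0
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                orf_start = None  # N-containing codon breaks the frame
            elif codon in STOPS:
                if orf_start is not None:
                    best = max(best, codon_i - orf_start)
                orf_start = None
            elif codon == "ATG" and orf_start is None:
                orf_start = codon_i
            codon_i += 1
    return best


def max_orf_length(sequence: str, strand: str = ".") -> int:
    """Longest ATG-initiated, stop-terminated reading frame, in amino acids.

    Counts codons from ATG up to but excluding the stop. Scans the given
    strand's 3 frames when the strand is known, else all 6 frames.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must be over A/C/G/T/N")
    if strand == "+":
        return _scan_frames(seq)
    rc = seq.translate(COMPLEMENT)[::-1]
    if strand == "-":
        return _scan_frames(rc)
    return max(_scan_frames(seq), _scan_frames(rc))


# ---------------------------------------------------------------- conservation

@dataclass
class ConservationTrack:
    """Per-base conservation probabilities in [0,1] per chromosome."""

    scores: dict[str, np.ndarray]

    def mean_score(self, iv: GenomicInterval) -> float:
        return float(self.scores[iv.chrom][iv.start : iv.end].mean())


def sample_matched_intervals(
    lengths, intergenic: IntervalSet, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Random intergenic loci, one per requested length, placed uniformly
    over all positions where an interval of that length fits in a gap."""
    gaps = [
        (chrom, int(s), int(e))
        for chrom, arr in intergenic.by_chrom.items()
        for s, e in arr
    ]
    out = []
    for L in lengths:
        eligible = [(c, s, e) for c, s, e in gaps if e - s >= L]
        if not eligible:
            raise ValueError(f"no intergenic gap can host an interval of {L} bp")
        slack = np.array([e - s - L + 1 for _, s, e in eligible], dtype=float)
        gi = rng.choice(len(eligible), p=slack / slack.sum())
        c, s, e = eligible[gi]
        start = int(rng.integers(s, e - L + 1))
        out.append(GenomicInterval(c, start, start + L))
    return out


@dataclass
class ConservationVerdict:
    p_values: list[float]
    significant: bool
    candidate_means: np.ndarray


def conservation_significance(
    candidates: list[GenomicInterval],
    track: ConservationTrack,
    intergenic: IntervalSet,
    n_repeats: int = 50,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    combine: str = "max",
) -> ConservationVerdict:
    """Resampling test of candidate conservation against matched random loci.

    Each repeat draws a random intergenic set of the same count and lengths,
    computes per-interval mean conservation for both sets and applies a
    one-sided two-sample Kolmogorov-Smirnov test (candidates stochastically
    greater). The verdict combines the ``n_repeats`` p-values with the
    max-p rule by default (most conservative; 'median' also available).
    """
    if rng is None:
        rng = np.random.default_rng()
    cand_means = np.array([track.mean_score(iv) for iv in candidates])
    lengths = [len(iv) for iv in candidates]
    ps = []
    for _ in range(n_repeats):
        rand = sample_matched_intervals(lengths, intergenic, rng)
        rand_means = np.array([track.mean_score(iv) for iv in rand])
        # alternative='less': CDF(candidates) below CDF(random), i.e.
        # candidate means stochastically greater
        p = float(stats.ks_2samp(cand_means, rand_means, alternative="less").pvalue)
        ps.append(p)
    stat = max(ps) if combine == "max" else float(np.median(ps))
    return ConservationVerdict(ps, stat < alpha, cand_means)


# ---------------------------------------------------------------- homology records

@dataclass(frozen=True)
class HomologyRecord:
    """One tabular alignment hit of a transfrag against an ncRNA database."""

    transfrag_id: str
    subject_id: str
    subject_class: str
    expect_value: float
    percent_identity: float


def filter_homology_records(
    records, max_expect: float = 0.01, min_identity: float = 95.0
) -> tuple[list[HomologyRecord], Counter]:
    """Accept hits with Expect <= 0.01 and identity >= 95%; tally per class."""
    accepted = [
        r
        for r in records
        if r.expect_value <= max_expect and r.percent_identity >= min_identity
    ]
    return accepted, Counter(r.subject_class for r in accepted)


# ---------------------------------------------------------------- candidates

@dataclass
class SnacRNACandidate:
    transfrag_id: str
    region: GenomicInterval
    category: str  # intronic | intergenic
    rpkm_by_cell: dict[str, float]
    passes_threshold: bool
    max_orf_aa: int | None
    coding_flag: bool
    mean_conservation: float | None
    differential_score: float
    log2_fold_change: float


def differential_rank(
    candidates: list[SnacRNACandidate],
    cell_a: str,
    cell_b: str,
    epsilon: float = 0.1,
) -> list[SnacRNACandidate]:
    """Sort candidates by differential RPKM (cell_a − cell_b), descending.

    The primary score is the RPKM difference; a shifted log2 fold change is
    reported alongside. Stable sort: input order breaks ties.
    """
    for c in candidates:
        a, b = c.rpkm_by_cell.get(cell_a, 0.0), c.rpkm_by_cell.get(cell_b, 0.0)
        c.differential_score = a - b
        c.log2_fold_change = float(np.log2((a + epsilon) / (b + epsilon)))
    return sorted(candidates, key=lambda c: -c.differential_score)


def screen_candidates(
    transfrags,
    categories: dict[str, str],
    rpkm_by_cell: dict[str, dict[str, float]],
    threshold_log10: float,
    sequences: dict[str, str] | None = None,
    inferred_strands: dict[str, str] | None = None,
    orf_aa_threshold: int = 100,
) -> list[SnacRNACandidate]:
    """Apply the abundance and coding-potential filters to intronic/intergenic
    transfrags.

    ``categories`` maps transfrag id ('chrom:start-end') to genomic context;
    exonic transfrags are excluded upstream and skipped here. A candidate
    passes the abundance filter when its max log10 RPKM over cell types
    meets the threshold; the coding flag marks ORFs longer than
    ``orf_aa_threshold`` amino acids.
    """
    out = []
    for t in transfrags:
        tid = f"{t.interval.chrom}:{t.interval.start}-{t.interval.end}"
        cat = categories.get(tid)
        if cat not in ("intronic", "intergenic"):
            continue
        rpkms = {cell: rpkm_by_cell[cell].get(tid, 0.0) for cell in rpkm_by_cell}
        best = max(rpkms.values())
        passes = best > 0 and np.log10(best) >= threshold_log10
        orf = None
        coding = False
        if sequences is not None and tid in sequences:
            strand = (inferred_strands or {}).get(tid, ".")
            if strand == "undetermined":
                strand = "."
            orf = max_orf_length(sequences[tid], strand)
            coding = orf > orf_aa_threshold
        out.append(
            SnacRNACandidate(
                transfrag_id=tid,
                region=t.interval,
                category=cat,
                rpkm_by_cell=rpkms,
                passes_threshold=bool(passes),
                max_orf_aa=orf,
                coding_flag=coding,
                mean_conservation=None,
                differential_score=0.0,
                log2_fold_change=0.0,
            )
        )
    return out
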