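"""Synthetic dual-fraction tiling-array / RNA-seq dataset with planted truth.

Emulates the experimental design the pipeline consumes: triplicate
probe intensities where canonical histone genes and planted ncRNA loci are
hot in the non-polyadenylated (NPA) fraction while mRNA exons are hot in
the polyadenylated (PA) fraction; stranded fixed-length reads with a
controllable antisense fraction; per-base conservation elevated at planted
ncRNA loci; promoter/body ChIP peak shapes; and qPCR Ct tables with a
planted splicing-efficiency shift. Every draw is fixed by the config seed;
each generator owns an independent seeded stream so stages can be rerun in
isolation.

The generator owns no analysis logic: planted truth tables are the ground
truth against which every downstream stage is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, build_genome_partition
from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .rnaseq import ReadSet
from .screen import ConservationTrack

# per-generator RNG stream ids (seed sequence spawn keys)
_S_GENOME, _S_PROBES, _S_READS, _S_CONS, _S_CHIP, _S_QPCR = range(1, 7)

CELL_TYPES = ("ESC", "NPC")
CHIP_MARKS = ("H3K4me3", "RNAPII", "H3K36me3", "H3K27me3", "H3K9me3")


@dataclass
class SyntheticConfig:
    """Experimental-design parameters for the synthetic dataset.

    Defaults describe a scaled-down two-chromosome genome dense enough for
    every pipeline stage: triplicate arrays, ~4M retained reads per sample
    (the depth at which log10 RPKM = 1 corresponds to ~4 reads per 100 nt),
    planted ncRNAs with mean length ~130 nt, and histone abundances whose
    5th percentile defines the screen threshold.
    """

    seed: int = 0
    chromosome_bp: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chr2": 300_000}
    )
    include_chrM: bool = True
    chrM_bp: int = 16_000
    tiling_step: int = 30
    probe_length: int = 25

    # annotation
    n_coding_genes: int = 40
    exons_per_gene: tuple[int, int] = (3, 7)
    exon_bp: tuple[int, int] = (150, 300)
    intron_bp: tuple[int, int] = (500, 1500)
    n_histone_genes: int = 12
    histone_bp: tuple[int, int] = (400, 800)
    n_repeats: int = 30
    repeat_bp: tuple[int, int] = (150, 500)
    n_rrna: int = 2
    rrna_bp: int = 1000

    # planted ncRNAs (length lognormal, mean ~130 nt)
    n_planted_intronic: int = 8
    n_planted_intergenic: int = 8
    n_above_threshold_intronic: int = 5
    n_above_threshold_intergenic: int = 5
    ncrna_len_mu: float = np.log(120.0)
    ncrna_len_sigma: float = 0.35
    ncrna_len_clip: tuple[int, int] = (100, 400)

    # abundance plan (log10 RPKM); histone 5th pct ~ 1.05 defines threshold
    histone_log10_rpkm_mean: float = 1.3
    histone_log10_rpkm_sd: float = 0.15
    npc_histone_shift: float = 0.8  # mild downregulation after differentiation
    above_multiplier: tuple[float, float] = (3.0, 6.0)
    below_multiplier: float = 0.1
    flagship_fold: float = 80.0  # strongest ESC/NPC differential locus

    # arrays: intensity = probe affinity (shared across fractions/replicates
    # within a cell type) x per-sample multiplicative noise
    n_replicates: int = 3
    background_log_mu: float = 4.0
    affinity_log_sigma: float = 0.35
    noise_log_sigma: float = 0.2
    hot_lift: float = 10.0
    pa_contamination: float = 0.25
    coding_on_fraction: float = 0.8

    # reads
    reads_per_sample: int = 4_000_000
    read_length: int = 50
    antisense_fraction: float = 0.0
    background_rpkm: float = 0.3
    five_prime_bias: float = 0.0  # 0 = uniform over exonic bp of debris reads
    chrm_read_fraction: float = 0.01
    rrna_read_fraction: float = 0.01
    repeat_read_fraction: float = 0.02

    # conservation
    conservation_bg_alpha: float = 1.0
    conservation_bg_beta: float = 9.0
    conservation_lift: float = 0.85

    # ChIP
    chip_reads_per_mark: int = 60_000
    chip_read_length: int = 50
    chip_background_fraction: float = 0.3
    tss_peak_sd: float = 300.0
    body_halfwidth: int = 1500

    # qPCR
    qpcr_genes: tuple[str, ...] = ("Drap1", "Gars", "Psmc4", "Phb2", "Eed")
    qpcr_effect_gene: str = "Eed"
    qpcr_effect_fold: float = 2.0
    qpcr_noise_sd: float = 0.1
    qpcr_sample_shift_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.antisense_fraction <= 1:
            raise ValueError("antisense_fraction must be in [0,1]")
        for name in ("n_coding_genes", "n_histone_genes", "n_planted_intronic",
                     "n_planted_intergenic", "reads_per_sample"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int, sub: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, sub])

    @property
    def threshold_log10_plan(self) -> float:
        """The planned histone 5th percentile the abundance plan is anchored to."""
        return self.histone_log10_rpkm_mean - 1.6449 * self.histone_log10_rpkm_sd


class CapacityError(RuntimeError):
    """Genome too small to place the requested features."""


# ----------------------------------------------------------------- genome

def generate_genome(
    config: SyntheticConfig,
) -> tuple[GenomeLayout, AnnotationSet, pd.DataFrame, IntervalSet]:
    """Place genes, planted ncRNAs, repeats and rRNA; return layout,
    annotation (with repeat mask), the planted-truth table and rRNA set."""
    rng = config.rng(_S_GENOME)
    lengths = dict(config.chromosome_bp)
    if config.include_chrM:
        lengths["chrM"] = config.chrM_bp
    layout = GenomeLayout(lengths, config.tiling_step, config.probe_length)
    chroms = list(config.chromosome_bp)

    # build the feature queue: coding genes and histones, shuffled
    feats = [("coding", i) for i in range(config.n_coding_genes)] + [
        ("histone", i) for i in range(config.n_histone_genes)
    ]
    rng.shuffle(feats)

    genes: list[GeneModel] = []
    ci = 0
    cursor = 500
    for kind, idx in feats:
        placed = False
        while ci < len(chroms):
            chrom = chroms[ci]
            gap = int(rng.integers(800, 3000))
            start = cursor + gap
            if kind == "coding":
                n_ex = int(rng.integers(*config.exons_per_gene, endpoint=True))
                ex_lens = rng.integers(*config.exon_bp, size=n_ex, endpoint=True)
                in_lens = rng.integers(*config.intron_bp, size=n_ex - 1, endpoint=True)
                span = int(ex_lens.sum() + in_lens.sum())
            else:
                span = int(rng.integers(*config.histone_bp, endpoint=True))
            if start + span <= lengths[chrom] - 500:
                strand = "+" if rng.random() < 0.5 else "-"
                if kind == "coding":
                    exons, pos = [], start
                    for j in range(n_ex):
                        exons.append(
                            GenomicInterval(chrom, pos, pos + int(ex_lens[j]), strand)
                        )
                        pos += int(ex_lens[j])
                        if j < n_ex - 1:
                            pos += int(in_lens[j])
                    gid = f"gene{idx:03d}"
                    biotype = "coding"
                else:
                    exons = [GenomicInterval(chrom, start, start + span, strand)]
                    gid = f"hist{idx:03d}"
                    biotype = "histone_canonical"
                genes.append(
                    GeneModel(
                        gid,
                        GenomicInterval(chrom, start, start + span, strand),
                        tuple(exons),
                        biotype,
                    )
                )
                cursor = start + span
                placed = True
                break
            ci += 1
            cursor = 500
        if not placed:
            raise CapacityError("genome too small for requested gene count")

    truth_rows = []
    occupied: list[tuple[str, int, int]] = []

    def _collides(chrom, s, e, pad=100):
        return any(c == chrom and s < oe + pad and e + pad > os_ for c, os_, oe in occupied)

    # planted abundances ------------------------------------------------
    base = 10.0 ** config.threshold_log10_plan

    def _ncrna_length():
        L = int(np.exp(rng.normal(config.ncrna_len_mu, config.ncrna_len_sigma)))
        return int(np.clip(L, *config.ncrna_len_clip))

    def _abundances(i, n_above, flagship):
        if i < n_above:
            mult = float(rng.uniform(*config.above_multiplier))
            if flagship and i == 0:
                esc = base * 10.0
                return esc, esc / config.flagship_fold
            ratio = float(rng.uniform(0.7, 1.4))
            return base * mult, base * mult * ratio
        return base * config.below_multiplier, base * config.below_multiplier

    # intronic ncRNAs: inside introns of coding genes, >=100 bp margins
    coding = [g for g in genes if g.biotype == "coding" and len(g.exons) > 1]
    for i in range(config.n_planted_intronic):
        for _ in range(500):
            g = coding[int(rng.integers(len(coding)))]
            introns = [
                (a.end, b.start) for a, b in zip(g.exons, g.exons[1:])
            ]
            s_in, e_in = introns[int(rng.integers(len(introns)))]
            L = _ncrna_length()
            if e_in - s_in < L + 220:
                continue
            start = int(rng.integers(s_in + 100, e_in - L - 100))
            chrom = g.interval.chrom
            if _collides(chrom, start, start + L):
                continue
            strand = g.strand if rng.random() < 0.9 else ("-" if g.strand == "+" else "+")
            esc, npc = _abundances(i, config.n_above_threshold_intronic, False)
            occupied.append((chrom, start, start + L))
            truth_rows.append(
                dict(locus_id=f"nci{i:03d}", kind="ncRNA", category="intronic",
                     chrom=chrom, start=start, end=start + L, strand=strand,
                     rpkm_esc=esc, rpkm_npc=npc, conserved=True,
                     epi_class="none", host_gene=g.gene_id)
            )
            break
        else:
            raise CapacityError("could not place intronic ncRNA")

    # intergenic ncRNAs: in gaps, >=300 bp from any gene
    gene_set = IntervalSet.from_intervals(g.interval for g in genes)
    gaps = [
        (chrom, int(s), int(e))
        for chrom, arr in gene_set.complement(layout).by_chrom.items()
        for s, e in arr
        if chrom in chroms
    ]
    epi_cycle = ("tss_peak", "body", "none")
    for i in range(config.n_planted_intergenic):
        for _ in range(500):
            chrom, gs, ge = gaps[int(rng.integers(len(gaps)))]
            L = _ncrna_length()
            if ge - gs < L + 620:
                continue
            start = int(rng.integers(gs + 300, ge - L - 300))
            if _collides(chrom, start, start + L, pad=200):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            esc, npc = _abundances(i, config.n_above_threshold_intergenic, True)
            occupied.append((chrom, start, start + L))
            truth_rows.append(
                dict(locus_id=f"ncg{i:03d}", kind="ncRNA", category="intergenic",
                     chrom=chrom, start=start, end=start + L, strand=strand,
                     rpkm_esc=esc, rpkm_npc=npc, conserved=True,
                     epi_class=epi_cycle[i % 3], host_gene="")
            )
            break
        else:
            raise CapacityError("could not place intergenic ncRNA")

    # histone truth rows (abundance + epigenetic class)
    for g in genes:
        if g.biotype != "histone_canonical":
            continue
        esc = 10.0 ** rng.normal(config.histone_log10_rpkm_mean, config.histone_log10_rpkm_sd)
        npc = config.npc_histone_shift * 10.0 ** rng.normal(
            config.histone_log10_rpkm_mean, config.histone_log10_rpkm_sd
        )
        truth_rows.append(
            dict(locus_id=g.gene_id, kind="histone", category="exonic",
                 chrom=g.interval.chrom, start=g.interval.start, end=g.interval.end,
                 strand=g.strand, rpkm_esc=esc, rpkm_npc=npc, conserved=False,
                 epi_class="tss_peak", host_gene=g.gene_id)
        )

    # repeats and rRNA in intergenic space clear of genes and planted loci
    repeat_ivs, rrna_ivs = [], []
    for n_feat, size_fn, bucket in (
        (config.n_repeats, lambda: int(rng.integers(*config.repeat_bp, endpoint=True)), repeat_ivs),
        (config.n_rrna, lambda: config.rrna_bp, rrna_ivs),
    ):
        for _ in range(n_feat):
            for _try in range(500):
                chrom, gs, ge = gaps[int(rng.integers(len(gaps)))]
                L = size_fn()
                if ge - gs < L + 320:
                    continue
                start = int(rng.integers(gs + 150, ge - L - 150))
                if _collides(chrom, start, start + L, pad=150):
                    continue
                occupied.append((chrom, start, start + L))
                bucket.append(GenomicInterval(chrom, start, start + L))
                break
            else:
                raise CapacityError("could not place repeat/rRNA feature")

    repeat_mask = IntervalSet.from_intervals(repeat_ivs)
    rrna = IntervalSet.from_intervals(rrna_ivs)
    annotation = build_genome_partition(genes, layout, repeat_mask=repeat_mask)
    truth = pd.DataFrame(truth_rows)
    return layout, annotation, truth, rrna


def gene_expression_truth(config: SyntheticConfig, annotation: AnnotationSet) -> pd.DataFrame:
    """Per coding gene: PA 'on' status per cell type and mRNA-debris weight."""
    rng = config.rng(_S_GENOME, 1)
    rows = []
    for g in annotation.genes:
        if g.biotype != "coding":
            continue
        rows.append(
            dict(
                gene_id=g.gene_id,
                expressed_esc=bool(rng.random() < config.coding_on_fraction),
                expressed_npc=bool(rng.random() < config.coding_on_fraction),
                debris_weight=float(rng.lognormal(0.0, 1.0)),
            )
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- probes

def _hot_mask(starts: np.ndarray, plen: int, loci: list[tuple[int, int]]) -> np.ndarray:
    """Probe is hot when its midpoint lies inside a hot locus."""
    mids = starts + plen // 2
    mask = np.zeros(len(starts), dtype=bool)
    for s, e in loci:
        mask |= (mids >= s) & (mids < e)
    return mask


def generate_probe_tracks(
    config: SyntheticConfig,
    layout: GenomeLayout,
    annotation: AnnotationSet,
    truth: pd.DataFrame,
    gene_truth: pd.DataFrame | None = None,
) -> dict[str, "object"]:
    """Triplicate NPA/PA probe intensity tracks per cell type.

    NPA intensities are lifted above background at histone exons and
    planted ncRNA loci in every replicate; PA intensities at those loci see
    only a contamination-scaled fraction of the lift, while PA is lifted at
    exons of expressed coding genes.
    """
    from .transfrags import ProbeTrack

    if gene_truth is None:
        gene_truth = gene_expression_truth(config, annotation)
    on_flags = gene_truth.set_index("gene_id")
    genes_by_id = annotation.genes_by_id()
    tracks = {}
    for cell_i, cell in enumerate(CELL_TYPES):
        rng = config.rng(_S_PROBES, cell_i)
        npa_hot = {c: [] for c in layout.chromosomes}
        for _, row in truth.iterrows():
            npa_hot[row.chrom].append((row.start, row.end))
        pa_hot = {c: [] for c in layout.chromosomes}
        col = f"expressed_{cell.lower()}"
        for gid in on_flags.index:
            if on_flags.loc[gid, col]:
                g = genes_by_id[gid]
                for e in g.exons:
                    pa_hot[e.chrom].append((e.start, e.end))

        positions, npa, pa = {}, {}, {}
        lift = config.hot_lift
        pa_lift = 1.0 + config.pa_contamination * (lift - 1.0)
        for chrom in layout.chromosomes:
            starts = layout.probe_starts(chrom)
            shape = (len(starts), config.n_replicates)
            # probe-sequence affinity is a property of the probe and is
            # shared between fractions and replicates of one hybridization
            # series; per-sample noise is independent
            affinity = rng.lognormal(config.background_log_mu,
                                     config.affinity_log_sigma, len(starts))
            noise_a = rng.lognormal(0.0, config.noise_log_sigma, shape)
            noise_b = rng.lognormal(0.0, config.noise_log_sigma, shape)
            m_npa = _hot_mask(starts, layout.probe_length, npa_hot[chrom])
            m_pa = _hot_mask(starts, layout.probe_length, pa_hot[chrom])
            a = affinity[:, None] * noise_a
            a[m_npa] *= lift
            b = affinity[:, None] * noise_b
            b[m_npa] *= pa_lift
            b[m_pa & ~m_npa] *= lift
            positions[chrom], npa[chrom], pa[chrom] = starts, a, b
        tracks[cell] = ProbeTrack(layout, positions, npa, pa, cell_type=cell)
    return tracks


# ----------------------------------------------------------------- reads

def generate_reads(
    config: SyntheticConfig,
    layout: GenomeLayout,
    annotation: AnnotationSet,
    truth: pd.DataFrame,
    cell: str,
    gene_truth: pd.DataFrame | None = None,
    reads_per_sample: int | None = None,
    antisense_fraction: float | None = None,
    rng_sub: int = 0,
) -> ReadSet:
    """Stranded fixed-length reads for one cell type.

    Exactly ``reads_per_sample`` clean reads are allocated multinomially:
    planted loci receive their RPKM-implied share, a small uniform
    background supplies the rest of the genome, and the remainder lands on
    exons of expressed coding genes (partially degraded mRNA carried over
    into the NPA fraction). Each locus read takes the locus strand, flipped
    with probability ``antisense_fraction``. Contaminant reads (chrM, rRNA,
    repeats) are added on top and are meant to be removed by filtering.
    """
    N = reads_per_sample if reads_per_sample is not None else config.reads_per_sample
    f_anti = (
        antisense_fraction if antisense_fraction is not None else config.antisense_fraction
    )
    cell_i = CELL_TYPES.index(cell)
    rng = config.rng(_S_READS, 100 * rng_sub + cell_i)
    L = config.read_length
    rcol = f"rpkm_{cell.lower()}"

    if gene_truth is None:
        gene_truth = gene_expression_truth(config, annotation)
    genes_by_id = annotation.genes_by_id()

    # source table: (kind, payload, strand, expected reads)
    sources = []
    for _, row in truth.iterrows():
        exp = row[rcol] * (row.end - row.start) * N / 1e9
        sources.append(("locus", (row.chrom, row.start, row.end), row.strand, exp))
    bg_exp = config.background_rpkm * layout.genome_bp * N / 1e9
    planted_total = sum(s[3] for s in sources) + bg_exp
    debris_total = max(N - planted_total, 0.0)
    col = f"expressed_{cell.lower()}"
    on = gene_truth[gene_truth[col]] if len(gene_truth) else gene_truth
    if debris_total > 0 and len(on) > 0 and on.debris_weight.sum() > 0:
        wsum = on.debris_weight.sum()
        for _, g in on.iterrows():
            gene = genes_by_id[g.gene_id]
            sources.append(
                ("debris", gene, gene.strand, debris_total * g.debris_weight / wsum)
            )
    else:
        bg_exp += debris_total  # no expressed genes: remainder stays diffuse
    sources.append(("background", None, ".", bg_exp))

    exps = np.array([s[3] for s in sources])
    counts = rng.multinomial(N, exps / exps.sum())

    chrom_names = list(layout.lengths)
    chrom_lens = np.array([layout.lengths[c] for c in chrom_names])
    chrom_offsets = np.concatenate([[0], np.cumsum(chrom_lens)])

    chroms_out, starts_out, strands_out = [], [], []

    def _emit(chrom_arr, start_arr, strand_arr):
        chroms_out.append(chrom_arr)
        starts_out.append(start_arr)
        strands_out.append(strand_arr)

    for (kind, payload, strand, _), n in zip(sources, counts):
        if n == 0:
            continue
        if kind == "locus":
            chrom, s, e = payload
            hi = max(e - L, s + 1)
            pos = rng.integers(s, hi, size=n)
            sense = np.full(n, strand)
        elif kind == "background":
            flat = rng.integers(0, chrom_offsets[-1], size=n)
            ci = np.searchsorted(chrom_offsets, flat, "right") - 1
            pos = flat - chrom_offsets[ci]
            pos = np.minimum(pos, chrom_lens[ci] - L)
            chrom_arr = np.array(chrom_names, dtype=object)[ci]
            sense = np.where(rng.random(n) < 0.5, "+", "-")
            _emit(chrom_arr, pos, sense)
            continue
        else:  # debris over exonic bp of one gene, optional 5' bias
            gene = payload
            ex = [(e0.start, e0.end) for e0 in gene.exons]
            lens = np.array([e1 - s1 for s1, e1 in ex])
            offs = np.concatenate([[0], np.cumsum(lens)])
            total = offs[-1]
            q = rng.random(n)
            if config.five_prime_bias > 0:
                # bias transcript-coordinate positions toward the 5' end
                q = q ** (1.0 + config.five_prime_bias)
            tpos = (q * total).astype(np.int64)
            if gene.strand == "-":
                tpos = total - 1 - tpos
            ei = np.searchsorted(offs, tpos, "right") - 1
            pos = np.array([ex[i][0] for i in ei]) + (tpos - offs[ei])
            pos = np.minimum(pos, layout.lengths[gene.interval.chrom] - L)
            chrom = gene.interval.chrom
            sense = np.full(n, gene.strand)
        chrom_arr = np.full(n, chrom, dtype=object)
        if f_anti > 0 and kind != "background":
            flip = rng.random(n) < f_anti
            sense = np.where(
                flip, np.where(sense == "+", "-", "+"), sense
            )
        _emit(chrom_arr, pos, sense)

    # chrM contaminant reads on top of the clean N (rRNA/repeat contaminants
    # are spiked separately by add_contaminant_reads)
    contam = []
    if config.include_chrM and config.chrm_read_fraction > 0:
        n = int(round(N * config.chrm_read_fraction))
        pos = rng.integers(0, layout.lengths["chrM"] - L, size=n)
        contam.append((np.full(n, "chrM", dtype=object), pos))

    all_chroms = np.concatenate(chroms_out) if chroms_out else np.empty(0, dtype=object)
    all_starts = np.concatenate(starts_out) if starts_out else np.empty(0, dtype=np.int64)
    all_strands = np.concatenate(strands_out) if strands_out else np.empty(0, dtype=object)
    for arr_c, arr_p in contam:
        all_chroms = np.concatenate([all_chroms, arr_c])
        all_starts = np.concatenate([all_starts, arr_p])
        all_strands = np.concatenate(
            [all_strands, np.where(rng.random(len(arr_c)) < 0.5, "+", "-")]
        )

    starts_map: dict[tuple[str, str], np.ndarray] = {}
    total = 0
    for chrom in layout.lengths:
        on_chrom = all_chroms == chrom
        for strand in ("+", "-"):
            sel = on_chrom & (all_strands == strand)
            if sel.any():
                starts_map[(chrom, strand)] = np.sort(all_starts[sel].astype(np.int64))
                total += int(sel.sum())
    return ReadSet(sample=cell, read_length=L, starts=starts_map, total_mapped=total)


def add_contaminant_reads(
    config: SyntheticConfig,
    reads: ReadSet,
    layout: GenomeLayout,
    rrna: IntervalSet,
    repeat_mask: IntervalSet,
    rng_sub: int = 50,
) -> ReadSet:
    """Spike rRNA- and repeat-overlapping reads on top of a clean ReadSet.

    These are the reads the region filter is expected to remove; chrM reads
    are already handled inside generate_reads.
    """
    rng = config.rng(_S_READS, 1000 + rng_sub)
    L = reads.read_length
    extra: list[GenomicInterval] = []
    for iset, frac in ((rrna, config.rrna_read_fraction),
                       (repeat_mask, config.repeat_read_fraction)):
        ivs = iset.to_intervals()
        if not ivs or frac <= 0:
            continue
        n = int(round(reads.total_mapped * frac))
        lens = np.array([len(iv) for iv in ivs], dtype=float)
        pick = rng.choice(len(ivs), size=n, p=lens / lens.sum())
        for i in pick:
            iv = ivs[i]
            hi = max(iv.end - L, iv.start + 1)
            s = int(rng.integers(iv.start, hi))
            extra.append(
                GenomicInterval(iv.chrom, s, s + L, "+" if rng.random() < 0.5 else "-")
            )
    by_key: dict[tuple[str, str], list[int]] = {}
    for iv in extra:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv.start)
    merged = dict(reads.starts)
    for key, starts in by_key.items():
        merged[key] = np.concatenate(
            [merged.get(key, np.empty(0, dtype=np.int64)),
             np.array(starts, dtype=np.int64)]
        )
    merged = {k: np.sort(np.asarray(v, dtype=np.int64)) for k, v in merged.items()}
    total = sum(len(v) for v in merged.values())
    return ReadSet(reads.sample, L, merged, total)


# ----------------------------------------------------------------- conservation

def generate_conservation(
    config: SyntheticConfig,
    layout: GenomeLayout,
    truth: pd.DataFrame,
    lift: float | None = None,
) -> ConservationTrack:
    """Per-base conservation: low-mean Beta background, planted ncRNA bases
    pulled toward 1 by the lift factor (score' = 1 - (1-score)(1-lift))."""
    rng = config.rng(_S_CONS)
    lift = config.conservation_lift if lift is None else lift
    scores = {
        chrom: rng.beta(
            config.conservation_bg_alpha, config.conservation_bg_beta, n
        ).astype(np.float32)
        for chrom, n in layout.lengths.items()
    }
    for _, row in truth.iterrows():
        if row.kind == "ncRNA" and row.conserved:
            seg = scores[row.chrom][row.start : row.end]
            scores[row.chrom][row.start : row.end] = 1.0 - (1.0 - seg) * (1.0 - lift)
    return ConservationTrack({c: a.astype(float) for c, a in scores.items()})


# ----------------------------------------------------------------- ChIP

def generate_chip_profiles(
    config: SyntheticConfig,
    layout: GenomeLayout,
    annotation: AnnotationSet,
    truth: pd.DataFrame,
) -> dict[str, ReadSet]:
    """Per-mark read sets realizing the planted epigenetic classes.

    tss_peak regions draw H3K4me3/RNAPII read positions from a Gaussian at
    the region's TSS (gene TSS for genes, center for intergenic loci);
    body regions draw H3K36me3 uniformly over the region body; 'none'
    regions and the repressive marks see only uniform background.
    """
    genes_by_id = annotation.genes_by_id()
    tss_regions, body_regions = [], []
    for _, row in truth.iterrows():
        if row.epi_class == "tss_peak":
            if row.host_gene and row.host_gene in genes_by_id:
                g = genes_by_id[row.host_gene]
                tss_regions.append((row.chrom, g.tss))
            else:
                tss_regions.append((row.chrom, (row.start + row.end) // 2))
        elif row.epi_class == "body":
            c = (row.start + row.end) // 2
            half = max((row.end - row.start) // 2, config.body_halfwidth)
            body_regions.append((row.chrom, c - half, c + half))

    out = {}
    for mark_i, mark in enumerate(CHIP_MARKS):
        rng = config.rng(_S_CHIP, mark_i)
        N = config.chip_reads_per_mark
        L = config.chip_read_length
        if mark in ("H3K4me3", "RNAPII") and tss_regions:
            n_sig = int(N * (1 - config.chip_background_fraction))
            targets = [tss_regions[i] for i in rng.integers(0, len(tss_regions), n_sig)]
            pos = np.array(
                [t[1] for t in targets]
            ) + rng.normal(0, config.tss_peak_sd, n_sig).astype(int)
            chroms = np.array([t[0] for t in targets], dtype=object)
        elif mark == "H3K36me3" and body_regions:
            n_sig = int(N * (1 - config.chip_background_fraction))
            idx = rng.integers(0, len(body_regions), n_sig)
            chroms = np.array([body_regions[i][0] for i in idx], dtype=object)
            lo = np.array([body_regions[i][1] for i in idx])
            hi = np.array([body_regions[i][2] for i in idx])
            pos = lo + (rng.random(n_sig) * (hi - lo)).astype(int)
        else:
            n_sig = 0
            chroms = np.empty(0, dtype=object)
            pos = np.empty(0, dtype=np.int64)
        # uniform background over the nuclear chromosomes
        n_bg = N - n_sig
        names = [c for c in layout.lengths if c != "chrM"]
        lens = np.array([layout.lengths[c] for c in names])
        offs = np.concatenate([[0], np.cumsum(lens)])
        flat = rng.integers(0, offs[-1], n_bg)
        ci = np.searchsorted(offs, flat, "right") - 1
        bg_pos = flat - offs[ci]
        bg_chroms = np.array(names, dtype=object)[ci]
        chroms = np.concatenate([chroms, bg_chroms])
        pos = np.concatenate([pos, bg_pos])
        strands = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        starts_map: dict[tuple[str, str], np.ndarray] = {}
        for chrom in names:
            clen = layout.lengths[chrom]
            onc = chroms == chrom
            for strand in ("+", "-"):
                sel = onc & (strands == strand)
                if sel.any():
                    p = np.clip(pos[sel].astype(np.int64), 0, clen - L)
                    starts_map[(chrom, strand)] = np.sort(p)
        out[mark] = ReadSet(mark, L, starts_map, int(sum(len(v) for v in starts_map.values())))
    return out


# ----------------------------------------------------------------- qPCR

def generate_qpcr(config: SyntheticConfig) -> pd.DataFrame:
    """Tidy Ct table for the U12/U2 splicing-efficiency assay.

    The effect gene's splicing efficiency is shifted ``qpcr_effect_fold``-
    fold upward in NPCs (both its U12 and its U2 control intron) by raising
    the unspliced Ct; per-sample constant shifts emulate loading differences
    that reference-gene normalization must cancel.
    """
    rng = config.rng(_S_QPCR)
    refs = {"Gapdh": 18.0, "18S": 10.0, "LaminB": 22.0}
    rows = []
    base_ct = {
        (g, ic): float(rng.uniform(18, 24))
        for g in config.qpcr_genes
        for ic in ("U12", "U2")
    }
    d_ct_effect = float(np.log2(config.qpcr_effect_fold))
    for cell in CELL_TYPES:
        for rep in (1, 2, 3):
            shift = float(rng.normal(0, config.qpcr_sample_shift_sd))
            for ref, ct0 in refs.items():
                rows.append(
                    dict(gene=f"REF:{ref}", intron_class="", amplicon="ref",
                         cell_type=cell, replicate=rep,
                         ct=ct0 + shift + rng.normal(0, config.qpcr_noise_sd))
                )
            for gene in config.qpcr_genes:
                for ic in ("U12", "U2"):
                    sp = base_ct[(gene, ic)]
                    un = sp + 4.0
                    if gene == config.qpcr_effect_gene and cell == "NPC":
                        un += d_ct_effect  # rarer pre-mRNA -> higher efficiency
                    for amp, ct in (("spliced", sp), ("unspliced", un)):
                        rows.append(
                            dict(gene=gene, intron_class=ic, amplicon=amp,
                                 cell_type=cell, replicate=rep,
                                 ct=ct + shift + rng.normal(0, config.qpcr_noise_sd))
                        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- dataset bundle

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    layout: GenomeLayout
    annotation: AnnotationSet
    truth: pd.DataFrame
    gene_truth: pd.DataFrame
    rrna: IntervalSet
    probe_tracks: dict
    reads: dict[str, ReadSet]
    conservation: ConservationTrack
    chip: dict[str, ReadSet]
    qpcr: pd.DataFrame


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every pipeline input with planted ground truth."""
    layout, annotation, truth, rrna = generate_genome(config)
    gene_truth = gene_expression_truth(config, annotation)
    tracks = generate_probe_tracks(config, layout, annotation, truth, gene_truth)
    reads = {}
    for cell in CELL_TYPES:
        clean = generate_reads(config, layout, annotation, truth, cell, gene_truth)
        reads[cell] = add_contaminant_reads(
            config, clean, layout, rrna, annotation.repeat_mask,
            rng_sub=CELL_TYPES.index(cell),
        )
    conservation = generate_conservation(config, layout, truth)
    chip = generate_chip_profiles(config, layout, annotation, truth)
    qpcr = generate_qpcr(config)
    return SyntheticDataset(
        config, layout, annotation, truth, gene_truth, rrna,
        tracks, reads, conservation, chip, qpcr,
    )


# ----------------------------------------------------------------- on-disk dataset

def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Emit every generated input in the pipeline's standard formats:
    chrom.sizes, the gene-annotation TSV, repeat/rRNA BEDs, bedGraph probe
    tracks per fraction x cell x replicate, BED6 reads, a per-base
    conservation bedGraph, ChIP BED6 per mark, the qPCR Ct table and the
    planted-truth TSVs."""
    from .io import (
        ensure_dir,
        write_annotation,
        write_bed,
        write_bedgraph,
        write_chrom_sizes,
    )

    out = ensure_dir(outdir)
    write_chrom_sizes(out / "chrom.sizes", dataset.layout.lengths)
    write_annotation(out / "genes.tsv", dataset.annotation.genes)
    write_bed(out / "repeats.bed", dataset.annotation.repeat_mask.to_intervals())
    write_bed(out / "rrna.bed", dataset.rrna.to_intervals())
    dataset.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    dataset.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
    dataset.qpcr.to_csv(out / "qpcr.tsv", sep="\t", index=False)

    probes = ensure_dir(out / "probes")
    for cell, track in dataset.probe_tracks.items():
        for frac, mats in (("NPA", track.npa), ("PA", track.pa)):
            for rep in range(track.n_replicates):
                tracks = {
                    chrom: (track.positions[chrom], mats[chrom][:, rep])
                    for chrom in track.positions
                }
                write_bedgraph(
                    probes / f"{cell}_{frac}_rep{rep + 1}.bedgraph",
                    tracks, span=dataset.layout.probe_length,
                    track_name=f"{cell} {frac} rep{rep + 1}",
                )

    reads_dir = ensure_dir(out / "reads")
    for cell, rs in dataset.reads.items():
        write_bed(reads_dir / f"{cell}.bed", rs.to_intervals())
    chip_dir = ensure_dir(out / "chip")
    for mark, rs in dataset.chip.items():
        write_bed(chip_dir / f"{mark}.bed", rs.to_intervals())

    cons = {
        chrom: (np.arange(len(arr)), arr)
        for chrom, arr in dataset.conservation.scores.items()
    }
    write_bedgraph(out / "conservation.bedgraph", cons, span=1)
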