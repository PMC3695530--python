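"""End-to-end orchestration of the NPA-transcriptome pipeline on a synthetic
dataset: transfrag calling, genomic-context enrichment, expression calls,
read quantification, the snacRNA screen, epigenetic profile clustering and
the splicing-efficiency report, with a reproducible run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation import AnnotationSet
from .epigenetics import build_profile_matrix, cluster_profiles, mean_cluster_profiles
from .expression import call_all_genes
from .genic_context import classify_all, enrichment_report, exon_bias_enrichment
from .intervals import GenomicInterval, IntervalSet
from .io import ensure_dir, write_bed
from .rnaseq import filter_reads, quantify_transfrags
from .screen import (
    conservation_significance,
    differential_rank,
    histone_rpkm_threshold,
    screen_candidates,
)
from .splicing import efficiency_report
from .synthetic import (
    CELL_TYPES,
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
)
from .transfrags import CallerConfig, call_transfrags, compare_transfrag_sets

log = logging.getLogger("snacrna")


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults reproduce the published analysis
    parameters (minrun 50, maxgap 40, >=3 probes, 5th-percentile histone
    threshold combined by mean, 100-aa ORF cutoff, 50 conservation repeats,
    10 kb / 50 bp / k=6 epigenetic clustering)."""

    seed: int = 0
    outdir: str = "snacrna_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    orf_aa_threshold: int = 100
    conservation_repeats: int = 50
    conservation_alpha: float = 0.05
    epi_window: int = 10_000
    epi_bin: int = 50
    epi_k: int = 6
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.synthetic.seed = self.seed


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    transfrags: dict
    venn: dict
    categories: dict
    enrichment: dict
    expression: dict
    quant: dict
    threshold_log10: float
    candidates: list
    conservation: object
    epi_matrix: object
    epi_profiles: dict
    splicing: pd.DataFrame
    outdir: Path
    manifest: dict


def _tid(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


def candidate_sequences(config: SyntheticConfig, layout, intervals) -> dict[str, str]:
    """Deterministic random nucleotide sequences for screened intervals.

    The synthetic genome carries no sequence; each interval gets an i.i.d.
    A/C/G/T string seeded by its coordinates so the ORF filter is exercised
    reproducibly.
    """
    chrom_index = {c: i for i, c in enumerate(layout.lengths)}
    out = {}
    for iv in intervals:
        rng = np.random.default_rng(
            [config.seed, 7, chrom_index[iv.chrom], iv.start, iv.end]
        )
        out[_tid(iv)] = "".join(
            "ACGT"[b] for b in rng.integers(0, 4, iv.end - iv.start)
        )
    return out


def run_all(config: PipelineConfig, write_outputs: bool = True) -> PipelineResult:
    """Run every stage on a freshly generated synthetic dataset."""
    logging.basicConfig(level=config.log_level)
    log.info("generating synthetic dataset (seed=%d)", config.seed)
    ds = generate_dataset(config.synthetic)
    ann: AnnotationSet = ds.annotation
    outdir = ensure_dir(config.outdir) if write_outputs else Path(config.outdir)

    # ---- transfrag calling -------------------------------------------
    transfrags = {}
    for cell in CELL_TYPES:
        tfs = call_transfrags(ds.probe_tracks[cell], config.caller, ann.repeat_mask)
        log.info("%s: %d transfrags after repeat masking", cell, len(tfs))
        transfrags[cell] = tfs
    venn = compare_transfrag_sets(transfrags["ESC"], transfrags["NPC"])

    # ---- genomic context ---------------------------------------------
    categories = {c: classify_all(transfrags[c], ann) for c in CELL_TYPES}
    enrichment = {
        c: {
            "context": enrichment_report(transfrags[c], ann),
            "exon_bias": exon_bias_enrichment(transfrags[c], ann.genes, ds.layout),
        }
        for c in CELL_TYPES
    }

    # ---- expression calls (PA fraction) ------------------------------
    expression = {
        c: call_all_genes(ann.genes, ds.probe_tracks[c], fraction="pa")
        for c in CELL_TYPES
    }

    # ---- read filtering and quantification ---------------------------
    quant = {}
    filtered = {}
    for cell in CELL_TYPES:
        fr = filter_reads(ds.reads[cell], "chrM", ds.rrna, ann.repeat_mask)
        log.info(
            "%s: %d of %d reads retained after region filtering",
            cell, fr.total_mapped, ds.reads[cell].total_mapped,
        )
        filtered[cell] = fr
        quant[cell] = quantify_transfrags(transfrags[cell], fr, ann)

    # ---- snacRNA screen ----------------------------------------------
    histone_exons = IntervalSet.from_intervals(
        e for g in ann.genes if g.biotype == "histone_canonical" for e in g.exons
    )
    hist_rpkms = {}
    for cell in CELL_TYPES:
        vals = [
            q.rpkm
            for q in quant[cell]
            if histone_exons.overlaps(q.region)
        ]
        hist_rpkms[cell] = np.array(vals)
    threshold = histone_rpkm_threshold(hist_rpkms)
    log.info("histone-calibrated log10 RPKM threshold: %.3f", threshold)

    # union transfrag catalogue across cell types for screening
    union, seen = [], set()
    for cell in CELL_TYPES:
        for t in transfrags[cell]:
            tid = _tid(t.interval)
            if tid not in seen:
                seen.add(tid)
                union.append(t)
    union_categories = classify_all(union, ann)
    # re-quantify every union region against both cell types' read sets so
    # cell-specific transfrag boundaries get a proper RPKM in each cell
    union_quant = {
        cell: quantify_transfrags(union, filtered[cell], ann) for cell in CELL_TYPES
    }
    rpkm_by_cell = {
        cell: {_tid(q.region): q.rpkm for q in union_quant[cell]}
        for cell in CELL_TYPES
    }
    strands = {}
    for cell in CELL_TYPES:
        for q in union_quant[cell]:
            strands.setdefault(_tid(q.region), q.inferred_strand)
    screen_input = [
        t for t in union if union_categories[_tid(t.interval)] != "exonic"
    ]
    seqs = candidate_sequences(
        config.synthetic, ds.layout, [t.interval for t in screen_input]
    )
    candidates = screen_candidates(
        screen_input, union_categories, rpkm_by_cell, threshold,
        sequences=seqs, inferred_strands=strands,
        orf_aa_threshold=config.orf_aa_threshold,
    )
    for c in candidates:
        c.mean_conservation = ds.conservation.mean_score(c.region)
    passing_intergenic = [
        c.region
        for c in candidates
        if c.category == "intergenic" and c.passes_threshold and not c.coding_flag
    ]
    cons = None
    if passing_intergenic:
        cons = conservation_significance(
            passing_intergenic, ds.conservation, ann.intergenic,
            n_repeats=config.conservation_repeats, alpha=config.conservation_alpha,
            rng=np.random.default_rng([config.seed, 8]),
        )
        log.info(
            "conservation: max p over %d repeats = %.3g (significant=%s)",
            config.conservation_repeats, max(cons.p_values), cons.significant,
        )
    candidates = differential_rank(candidates, "ESC", "NPC")

    # ---- epigenetic profiles -----------------------------------------
    epi_regions = [
        GenomicInterval(g.interval.chrom, g.interval.start, g.interval.end)
        for g in ann.genes
        if g.biotype == "histone_canonical"
    ] + passing_intergenic
    epi_matrix = build_profile_matrix(
        epi_regions, ds.chip, ds.layout, config.epi_window, config.epi_bin
    )
    k = min(config.epi_k, len(epi_regions))
    cluster_profiles(epi_matrix, k=k, seed=config.seed)
    epi_profiles = mean_cluster_profiles(epi_matrix)

    # ---- splicing efficiency -----------------------------------------
    splicing = efficiency_report(ds.qpcr, "ESC", "NPC")

    result = PipelineResult(
        config=config, dataset=ds, transfrags=transfrags, venn=venn,
        categories=categories, enrichment=enrichment, expression=expression,
        quant=quant, threshold_log10=float(threshold), candidates=candidates,
        conservation=cons, epi_matrix=epi_matrix, epi_profiles=epi_profiles,
        splicing=splicing, outdir=outdir, manifest={},
    )
    if write_outputs:
        result.manifest = write_results(result)
    return result


# ---------------------------------------------------------------- outputs

def _enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(category=r.category, observed=r.observed_count,
                 total=r.total_count, genome_fraction=r.genome_fraction,
                 fold_enrichment=r.fold_enrichment, p_value=r.p_value,
                 p_adjusted=r.p_adjusted)
            for r in results
        ]
    )


def write_results(result: PipelineResult) -> dict:
    """Write all stage outputs plus a manifest with parameter echo and
    sha256 hashes of every emitted file."""
    outdir = ensure_dir(result.outdir)
    cfg = result.config
    files = []

    for cell, tfs in result.transfrags.items():
        p = outdir / f"transfrags_{cell}.bed"
        cats = result.categories[cell]
        write_bed(
            p,
            [
                (t.interval, f"{cats[_tid(t.interval)]}", t.probe_count)
                for t in tfs
            ],
            track_name=f"NPA transfrags {cell}",
        )
        files.append(p)

    p = outdir / "venn.tsv"
    pd.DataFrame(
        [{k: len(v) for k, v in result.venn.items()}]
    ).to_csv(p, sep="\t", index=False)
    files.append(p)

    for cell in result.enrichment:
        for key, res in result.enrichment[cell].items():
            p = outdir / f"{key}_{cell}.tsv"
            _enrichment_frame(res).to_csv(p, sep="\t", index=False, float_format="%.6g")
            files.append(p)

    for cell, calls in result.expression.items():
        p = outdir / f"expression_{cell}.tsv"
        pd.DataFrame([asdict(c) for c in calls]).to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        )
        files.append(p)

    for cell, quants in result.quant.items():
        p = outdir / f"quant_{cell}.tsv"
        pd.DataFrame(
            [
                dict(region=_tid(q.region), reads_plus=q.reads_plus,
                     reads_minus=q.reads_minus, rpkm=q.rpkm,
                     validated=q.validated, inferred_strand=q.inferred_strand,
                     orientation=q.orientation_vs_host, host_gene=q.host_gene)
                for q in quants
            ]
        ).to_csv(p, sep="\t", index=False, float_format="%.6g")
        files.append(p)

    p = outdir / "snacrna_candidates.tsv"
    pd.DataFrame(
        [
            dict(transfrag_id=c.transfrag_id, category=c.category,
                 rpkm_esc=c.rpkm_by_cell.get("ESC", 0.0),
                 rpkm_npc=c.rpkm_by_cell.get("NPC", 0.0),
                 passes_threshold=c.passes_threshold, max_orf_aa=c.max_orf_aa,
                 coding_flag=c.coding_flag, mean_conservation=c.mean_conservation,
                 differential_score=c.differential_score,
                 log2_fold_change=c.log2_fold_change)
            for c in result.candidates
        ]
    ).to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(p)

    if result.conservation is not None:
        p = outdir / "conservation_pvalues.tsv"
        pd.DataFrame(
            dict(repeat=np.arange(1, len(result.conservation.p_values) + 1),
                 ks_p=result.conservation.p_values)
        ).to_csv(p, sep="\t", index=False, float_format="%.6g")
        files.append(p)

    p = outdir / "epi_clusters.tsv"
    pd.DataFrame(
        dict(
            region=[_tid(r) for r in result.epi_matrix.regions],
            cluster=result.epi_matrix.cluster_labels,
            truncated=result.epi_matrix.truncated,
        )
    ).to_csv(p, sep="\t", index=False)
    files.append(p)

    p = outdir / "epi_mean_profiles.tsv"
    rows = []
    for lab, marks in result.epi_profiles.items():
        for mark, vec in marks.items():
            rows.append(
                dict(cluster=lab, mark=mark,
                     **{f"bin{i}": v for i, v in enumerate(vec)})
            )
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(p)

    p = outdir / "splicing.tsv"
    result.splicing.to_csv(p, sep="\t", index=False, float_format="%.6g")
    files.append(p)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "caller": asdict(cfg.caller),
            "orf_aa_threshold": cfg.orf_aa_threshold,
            "conservation_repeats": cfg.conservation_repeats,
            "conservation_alpha": cfg.conservation_alpha,
            "epi_window": cfg.epi_window,
            "epi_bin": cfg.epi_bin,
            "epi_k": cfg.epi_k,
            "threshold_log10": result.threshold_log10,
        },
        "counts": {
            "transfrags": {c: len(t) for c, t in result.transfrags.items()},
            "candidates": len(result.candidates),
        },
        "output_hashes": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(files)
        },
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------- config file

def load_config_file(path) -> dict:
    """Flat `key = value` config with '#' comments; values parsed as JSON
    scalars when possible, else kept as strings."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            try:
                out[key] = json.loads(val)
            except json.JSONDecodeError:
                out[key] = val
    return out


_KNOWN_KEYS = {
    "seed", "outdir", "noise_quantile", "minrun", "maxgap", "min_probes",
    "orf_aa_threshold", "conservation_repeats", "conservation_alpha",
    "epi_window", "epi_bin", "epi_k", "reads_per_sample", "antisense_fraction",
    "log_level",
}


def build_pipeline_config(**overrides) -> PipelineConfig:
    """PipelineConfig from flat keys (config file and/or CLI overrides)."""
    unknown = set(overrides) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(
        seed=int(overrides.get("seed", 0)),
        outdir=str(overrides.get("outdir", "snacrna_run")),
        orf_aa_threshold=int(overrides.get("orf_aa_threshold", 100)),
        conservation_repeats=int(overrides.get("conservation_repeats", 50)),
        conservation_alpha=float(overrides.get("conservation_alpha", 0.05)),
        epi_window=int(overrides.get("epi_window", 10_000)),
        epi_bin=int(overrides.get("epi_bin", 50)),
        epi_k=int(overrides.get("epi_k", 6)),
        log_level=str(overrides.get("log_level", "INFO")),
    )
    cfg.caller = CallerConfig(
        noise_quantile=float(overrides.get("noise_quantile", 0.90)),
        minrun=int(overrides.get("minrun", 50)),
        maxgap=int(overrides.get("maxgap", 40)),
        min_probes=int(overrides.get("min_probes", 3)),
    )
    if "reads_per_sample" in overrides:
        cfg.synthetic.reads_per_sample = int(overrides["reads_per_sample"])
    if "antisense_fraction" in overrides:
        cfg.synthetic.antisense_fraction = float(overrides["antisense_fraction"])
    return cfg
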