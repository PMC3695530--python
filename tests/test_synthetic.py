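"""Generator contracts: determinism, counts, planted signal directions."""

import numpy as np
import pandas as pd
import pytest

from snacrna.intervals import GenomicInterval
from snacrna.rnaseq import count_reads
from snacrna.synthetic import (
    SyntheticConfig,
    generate_conservation,
    generate_dataset,
    generate_genome,
    generate_probe_tracks,
    generate_reads,
    gene_expression_truth,
)


def test_same_seed_reproduces_dataset_exactly():
    a = generate_dataset(SyntheticConfig(seed=3, reads_per_sample=30_000))
    b = generate_dataset(SyntheticConfig(seed=3, reads_per_sample=30_000))
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.qpcr, b.qpcr)
    for chrom in a.layout.lengths:
        assert np.array_equal(a.probe_tracks["ESC"].npa[chrom], b.probe_tracks["ESC"].npa[chrom])
        assert np.array_equal(a.conservation.scores[chrom], b.conservation.scores[chrom])
    for key in a.reads["NPC"].starts:
        assert np.array_equal(a.reads["NPC"].starts[key], b.reads["NPC"].starts[key])


def test_different_seed_changes_draws():
    a = generate_genome(SyntheticConfig(seed=1))[2]
    b = generate_genome(SyntheticConfig(seed=2))[2]
    assert not a.equals(b)


def test_zero_planted_ncrnas_gives_empty_ncrna_truth():
    cfg = SyntheticConfig(seed=0, n_planted_intronic=0, n_planted_intergenic=0)
    _, _, truth, _ = generate_genome(cfg)
    assert (truth.kind == "ncRNA").sum() == 0


def test_histone_count_and_structure():
    cfg = SyntheticConfig(seed=4, n_histone_genes=10)
    _, ann, _, _ = generate_genome(cfg)
    histones = [g for g in ann.genes if g.biotype == "histone_canonical"]
    assert len(histones) == 10
    assert all(g.single_exon for g in histones)


def test_genes_do_not_overlap():
    _, ann, _, _ = generate_genome(SyntheticConfig(seed=9))
    by_chrom = {}
    for g in ann.genes:
        by_chrom.setdefault(g.interval.chrom, []).append(g.interval)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
        for x, y in zip(ivs, ivs[1:]):
            assert x.end <= y.start


class TestProbeTracks:
    def test_histone_npa_over_pa_ratio_above_one(self, dataset):
        ds = dataset
        for cell, track in ds.probe_tracks.items():
            ratios = []
            for g in ds.annotation.genes:
                if g.biotype != "histone_canonical":
                    continue
                chrom = g.interval.chrom
                starts = track.positions[chrom]
                mids = starts + ds.layout.probe_length // 2
                sel = (mids >= g.interval.start) & (mids < g.interval.end)
                ratios.append(track.npa[chrom][sel].mean() / track.pa[chrom][sel].mean())
            assert np.mean(ratios) > 1.0
            assert min(ratios) > 1.0

    def test_zero_contamination_leaves_pa_at_background(self):
        cfg = SyntheticConfig(seed=8, pa_contamination=0.0)
        layout, ann, truth, _ = generate_genome(cfg)
        tracks = generate_probe_tracks(cfg, layout, ann, truth)
        track = tracks["ESC"]
        hist = [g for g in ann.genes if g.biotype == "histone_canonical"]
        hot_vals, bg_vals = [], []
        for chrom in layout.chromosomes:
            starts = track.positions[chrom]
            mids = starts + layout.probe_length // 2
            hot = np.zeros(len(starts), dtype=bool)
            for g in hist:
                if g.interval.chrom == chrom:
                    hot |= (mids >= g.interval.start) & (mids < g.interval.end)
            hot_vals.append(track.pa[chrom][hot])
            bg_vals.append(track.pa[chrom][~hot])
        hot_mean = np.concatenate([v.ravel() for v in hot_vals]).mean()
        bg_mean = np.concatenate([v.ravel() for v in bg_vals]).mean()
        # PA at histone exons is statistically indistinguishable from
        # background when the contamination factor is zero
        assert hot_mean / bg_mean < 1.15


class TestReads:
    def _two_locus_setup(self, esc_a=1e9, esc_b=1e8):
        cfg = SyntheticConfig(
            seed=10, n_planted_intronic=0, n_planted_intergenic=2,
            n_above_threshold_intergenic=2, reads_per_sample=50_000,
            background_rpkm=0.0, coding_on_fraction=0.0,
        )
        layout, ann, truth, _ = generate_genome(cfg)
        truth = truth[truth.kind == "ncRNA"].reset_index(drop=True)
        truth.loc[0, ["rpkm_esc", "rpkm_npc"]] = esc_a
        truth.loc[1, ["rpkm_esc", "rpkm_npc"]] = esc_b
        # equalize lengths so counts compare the abundances directly
        truth.loc[1, "end"] = truth.loc[1, "start"] + (
            truth.loc[0, "end"] - truth.loc[0, "start"]
        )
        gt = gene_expression_truth(cfg, ann)
        return cfg, layout, ann, truth, gt

    def test_total_clean_reads_conserved(self):
        cfg, layout, ann, truth, gt = self._two_locus_setup()
        reads = generate_reads(cfg, layout, ann, truth, "ESC", gene_truth=gt)
        n_clean = cfg.reads_per_sample
        n_chrm = int(round(n_clean * cfg.chrm_read_fraction))
        assert reads.total_mapped == n_clean + n_chrm

    def test_ten_to_one_expression_recovered_in_counts(self):
        cfg, layout, ann, truth, gt = self._two_locus_setup()
        reads = generate_reads(cfg, layout, ann, truth, "ESC", gene_truth=gt)
        counts = [
            count_reads(GenomicInterval(r.chrom, r.start, r.end), reads)
            for r in truth.itertuples()
        ]
        ratio = counts[0] / counts[1]
        # 3 binomial SD around the planted 10:1
        n, p = sum(counts), 10 / 11
        sd = np.sqrt(n * p * (1 - p))
        assert abs(counts[0] - n * p) < 3 * sd, ratio

    def test_zero_antisense_fraction_gives_all_sense_reads(self):
        cfg, layout, ann, truth, gt = self._two_locus_setup(esc_a=1e9, esc_b=1e9)
        reads = generate_reads(
            cfg, layout, ann, truth, "ESC", gene_truth=gt, antisense_fraction=0.0
        )
        for r in truth.itertuples():
            region = GenomicInterval(r.chrom, r.start, r.end)
            anti = count_reads(region, reads, "minus" if r.strand == "+" else "plus")
            assert anti == 0

    def test_full_antisense_flips_every_locus_read(self):
        cfg, layout, ann, truth, gt = self._two_locus_setup(esc_a=1e9, esc_b=1e9)
        reads = generate_reads(
            cfg, layout, ann, truth, "ESC", gene_truth=gt, antisense_fraction=1.0
        )
        for r in truth.itertuples():
            region = GenomicInterval(r.chrom, r.start, r.end)
            sense = count_reads(region, reads, "plus" if r.strand == "+" else "minus")
            assert sense == 0


class TestConservationTrack:
    def test_scores_bounded_and_lift_direction(self, dataset):
        ds = dataset
        for arr in ds.conservation.scores.values():
            assert arr.min() >= 0 and arr.max() <= 1
        nc = ds.truth[ds.truth.kind == "ncRNA"]
        planted = np.concatenate(
            [ds.conservation.scores[r.chrom][r.start : r.end] for r in nc.itertuples()]
        )
        background = ds.conservation.scores["chr1"]
        assert planted.mean() > 5 * background.mean()

    def test_zero_lift_leaves_background_distribution(self):
        cfg = SyntheticConfig(seed=12)
        layout, ann, truth, _ = generate_genome(cfg)
        track = generate_conservation(cfg, layout, truth, lift=0.0)
        nc = truth[truth.kind == "ncRNA"]
        planted = np.concatenate(
            [track.scores[r.chrom][r.start : r.end] for r in nc.itertuples()]
        )
        assert abs(planted.mean() - 0.1) < 0.03  # Beta(1,9) background mean

    def test_full_lift_saturates_to_one(self):
        cfg = SyntheticConfig(seed=12)
        layout, ann, truth, _ = generate_genome(cfg)
        track = generate_conservation(cfg, layout, truth, lift=1.0)
        r = truth[truth.kind == "ncRNA"].iloc[0]
        assert np.allclose(track.scores[r.chrom][r.start : r.end], 1.0)


def test_capacity_error_when_genome_too_small():
    cfg = SyntheticConfig(seed=0, chromosome_bp={"chr1": 20_000}, n_coding_genes=40)
    from snacrna.synthetic import CapacityError

    with pytest.raises(CapacityError):
        generate_genome(cfg)
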