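"""Probe calling and transfrag assembly against brute-force oracles."""

import numpy as np
import pytest

from snacrna.intervals import GenomeLayout, GenomicInterval, IntervalSet
from snacrna.transfrags import (
    CallerConfig,
    ProbeTrack,
    Transfrag,
    assemble_transfrags,
    call_positive_probes,
    call_transfrags,
    compare_transfrag_sets,
    mask_repeats,
)

LAYOUT = GenomeLayout({"chr1": 100_000}, tiling_step=30, probe_length=25)
CFG = CallerConfig()


def brute_force_chains(starts, plen, cfg):
    """Independent enumerator: all maximal contiguous runs whose internal
    gaps are <= maxgap, filtered by minrun span and probe count."""
    starts = sorted(starts)
    chains, cur = [], []
    for s in starts:
        if cur and s - (cur[-1] + plen) > cfg.maxgap:
            chains.append(cur)
            cur = []
        cur.append(s)
    if cur:
        chains.append(cur)
    out = []
    for ch in chains:
        span = ch[-1] + plen - ch[0]
        if span >= cfg.minrun and len(ch) >= cfg.min_probes:
            out.append((ch[0], ch[-1] + plen, len(ch)))
    return out


def _track(npa, pa):
    """Single-chromosome track from per-probe replicate tuples."""
    npa = np.asarray(npa, dtype=float)
    pa = np.asarray(pa, dtype=float)
    pos = np.arange(len(npa)) * 30
    return ProbeTrack(LAYOUT, {"chr1": pos}, {"chr1": npa}, {"chr1": pa})


class TestPositiveProbes:
    def test_both_criteria_in_all_replicates(self):
        t = _track([[5, 6, 5]], [[1, 1, 1]])
        mask = call_positive_probes(t, CFG, thresholds=[2, 2, 2])
        assert mask["chr1"].tolist() == [True]

    def test_noise_failure_in_one_replicate_vetoes(self):
        t = _track([[5, 6, 1]], [[1, 1, 0.5]])
        mask = call_positive_probes(t, CFG, thresholds=[2, 2, 2])
        assert mask["chr1"].tolist() == [False]

    def test_pa_exceeding_npa_in_one_replicate_vetoes(self):
        t = _track([[5, 6, 5]], [[1, 7, 1]])
        mask = call_positive_probes(t, CFG, thresholds=[2, 2, 2])
        assert mask["chr1"].tolist() == [False]

    def test_quantile_threshold_is_per_replicate(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(0, 1, 500)
        npa = np.repeat(base[:, None], 3, axis=1)
        npa[:, 1] *= 100.0  # one replicate on a different scale
        t = _track(npa, np.zeros_like(npa))
        mask = call_positive_probes(t, CFG)
        # identical probe ranking per replicate: the scale difference must
        # not matter, and exactly the top ~10% pass in all replicates
        assert 45 <= mask["chr1"].sum() <= 50

    def test_replicate_mismatch_raises(self):
        with pytest.raises(ValueError, match="replicate"):
            ProbeTrack(
                LAYOUT,
                {"chr1": np.array([0])},
                {"chr1": np.ones((1, 3))},
                {"chr1": np.ones((1, 2))},
            )


class TestAssembly:
    def test_no_positive_probes(self):
        assert assemble_transfrags({"chr1": np.array([])}, LAYOUT, CFG) == []

    def test_three_probe_chain(self):
        (tf,) = assemble_transfrags({"chr1": np.array([100, 130, 160])}, LAYOUT, CFG)
        assert (tf.interval.start, tf.interval.end, tf.probe_count) == (100, 185, 3)

    def test_two_probe_chain_discarded(self):
        assert assemble_transfrags({"chr1": np.array([100, 130])}, LAYOUT, CFG) == []

    def test_chain_splits_at_maxgap_and_singleton_dropped(self):
        tfs = assemble_transfrags(
            {"chr1": np.array([100, 130, 160, 230])}, LAYOUT, CFG
        )
        # gap 230-185=45 > 40 splits; the 230 singleton is discarded
        assert len(tfs) == 1 and tfs[0].interval.end == 185

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(5)
        grid = np.arange(0, 100_000 - 25, 30)
        for _ in range(200):
            starts = np.sort(rng.choice(grid, size=rng.integers(0, 60), replace=False))
            got = assemble_transfrags({"chr1": starts}, LAYOUT, CFG)
            expect = brute_force_chains(starts.tolist(), 25, CFG)
            assert [(t.interval.start, t.interval.end, t.probe_count) for t in got] == expect

    def test_min_probes_monotonicity(self):
        rng = np.random.default_rng(9)
        grid = np.arange(0, 100_000 - 25, 30)
        starts = np.sort(rng.choice(grid, size=300, replace=False))
        counts = [
            len(assemble_transfrags({"chr1": starts}, LAYOUT,
                                    CallerConfig(min_probes=k)))
            for k in (1, 2, 3, 5, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_maxgap_monotonicity_on_prefilter_chains(self):
        rng = np.random.default_rng(10)
        grid = np.arange(0, 100_000 - 25, 30)
        starts = np.sort(rng.choice(grid, size=300, replace=False))
        chain_counts = [
            len(assemble_transfrags({"chr1": starts}, LAYOUT,
                                    CallerConfig(minrun=1, min_probes=1, maxgap=g)))
            for g in (0, 10, 40, 100, 400)
        ]
        assert chain_counts == sorted(chain_counts, reverse=True)

    def test_order_independence(self):
        starts = np.array([400, 100, 130, 160, 430, 460])
        a = assemble_transfrags({"chr1": starts}, LAYOUT, CFG)
        b = assemble_transfrags({"chr1": starts[::-1]}, LAYOUT, CFG)
        assert a == b


class TestFiltersAndComparison:
    def _tf(self, start, end):
        return Transfrag(GenomicInterval("chr1", start, end), probe_count=3)

    def test_mask_repeats_rules(self):
        tfs = [self._tf(100, 200), self._tf(300, 400), self._tf(500, 600)]
        empty = IntervalSet.from_intervals([])
        assert mask_repeats(tfs, empty) == tfs
        mask = IntervalSet.from_intervals(
            [GenomicInterval("chr1", 280, 450), GenomicInterval("chr1", 599, 650)]
        )
        # full containment and 1-bp overlap both remove the transfrag
        assert mask_repeats(tfs, mask) == [tfs[0]]

    def test_compare_identical_and_disjoint_sets(self):
        a = [self._tf(0, 100), self._tf(300, 400)]
        venn = compare_transfrag_sets(a, a)
        assert len(venn["shared_a"]) == 2 and not venn["unique_a"]
        b = [self._tf(1000, 1100)]
        venn = compare_transfrag_sets(a, b)
        assert not venn["shared_a"] and len(venn["unique_b"]) == 1

    def test_compare_matches_bitmap_oracle(self):
        rng = np.random.default_rng(4)

        def rand_set(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 9_000))
                out.append(self._tf(s, s + int(rng.integers(50, 300))))
            return out

        for _ in range(20):
            a, b = rand_set(15), rand_set(15)
            venn = compare_transfrag_sets(a, b)
            mask_b = np.zeros(10_000, dtype=bool)
            for t in b:
                mask_b[t.interval.start : t.interval.end] = True
            expect_shared = [
                t for t in a if mask_b[t.interval.start : t.interval.end].any()
            ]
            assert venn["shared_a"] == expect_shared
            assert len(venn["shared_a"]) + len(venn["unique_a"]) == len(a)


def test_histone_recall_on_synthetic_arrays(dataset):
    """Every planted single-exon histone gene is hit by >=1 transfrag."""
    ann = dataset.annotation
    for cell, track in dataset.probe_tracks.items():
        tfs = call_transfrags(track, CallerConfig(), ann.repeat_mask)
        iset = IntervalSet.from_intervals(t.interval for t in tfs)
        for g in ann.genes:
            if g.biotype == "histone_canonical":
                assert iset.overlaps(g.interval), (cell, g.gene_id)
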