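"""snacRNA screen: threshold calibration, ORF scan, conservation resampling,
homology filtering and differential ranking."""

import numpy as np
import pytest

from snacrna.intervals import GenomicInterval, IntervalSet
from snacrna.screen import (
    ConservationTrack,
    HomologyRecord,
    SnacRNACandidate,
    conservation_significance,
    differential_rank,
    filter_homology_records,
    histone_rpkm_threshold,
    max_orf_length,
    sample_matched_intervals,
)


class TestThreshold:
    def test_constant_distribution(self):
        thr = histone_rpkm_threshold({"ESC": np.full(10, 10.0), "NPC": np.full(8, 10.0)})
        assert thr == pytest.approx(1.0)

    def test_mean_of_per_cell_thresholds(self):
        thr = histone_rpkm_threshold(
            {"ESC": np.full(10, 10**0.9), "NPC": np.full(10, 10**1.1)}
        )
        assert thr == pytest.approx(1.0)

    def test_95pct_of_histones_at_or_above_own_percentile(self):
        rng = np.random.default_rng(0)
        arr = 10 ** rng.normal(1.3, 0.2, 200)
        thr = histone_rpkm_threshold({"only": arr})
        assert np.mean(np.log10(arr) >= thr) >= 0.95

    def test_zero_rpkms_excluded_with_warning(self):
        arr = np.concatenate([np.full(19, 10.0), [0.0]])
        with pytest.warns(UserWarning, match="zero-RPKM"):
            assert histone_rpkm_threshold({"c": arr}) == pytest.approx(1.0)

    def test_empty_histone_set_raises(self):
        with pytest.raises(ValueError):
            histone_rpkm_threshold({"c": np.array([])})


def orf_oracle(seq):
    """Brute-force: enumerate every ATG..stop pair in all 6 frames."""
    comp = str.maketrans("ACGTN", "TGCAN")
    best = 0
    for s in (seq, seq.translate(comp)[::-1]):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            for i, c in enumerate(codons):
                if c != "ATG":
                    continue
                for j in range(i, len(codons)):
                    if "N" in codons[j]:
                        break  # frame broken before any stop
                    if codons[j] in ("TAA", "TAG", "TGA"):
                        best = max(best, j - i)
                        break
    return best


class TestOrfScan:
    def test_no_atg(self):
        assert max_orf_length("CCCCCCCCC") == 0

    def test_minimal_orf(self):
        assert max_orf_length("ATGAAATAA", "+") == 2

    def test_unterminated_orf_not_counted(self):
        assert max_orf_length("ATGAAAAAA", "+") == 0

    def test_n_breaks_frame(self):
        assert max_orf_length("ATGANATAA", "+") == 0

    def test_reverse_strand(self):
        # reverse complement of ATGAAATAA is TTATTTCAT
        assert max_orf_length("TTATTTCAT", "-") == 2
        assert max_orf_length("TTATTTCAT", "+") == 0
        assert max_orf_length("TTATTTCAT") == 2  # unknown strand scans both

    def test_101_codon_orf_flags_coding(self):
        seq = "ATG" + "GCT" * 100 + "TAA"
        assert max_orf_length(seq, "+") == 101

    def test_matches_enumeration_oracle_on_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            n = int(rng.integers(10, 200))
            seq = "".join("ACGTN"[b] for b in rng.choice(5, n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            assert max_orf_length(seq) == orf_oracle(seq)

    def test_invalid_alphabet_rejected(self):
        with pytest.raises(ValueError):
            max_orf_length("ATGXXX")


@pytest.fixture(scope="module")
def intergenic_space():
    return IntervalSet.from_intervals(
        [GenomicInterval("chr1", 0, 60_000), GenomicInterval("chr2", 0, 40_000)]
    )


class TestConservation:
    def _track(self, rng, n=100_000, lift_regions=()):
        scores = {"chr1": rng.beta(1, 9, 60_000), "chr2": rng.beta(1, 9, 40_000)}
        for chrom, s, e in lift_regions:
            scores[chrom][s:e] = 1.0 - (1.0 - scores[chrom][s:e]) * 0.1
        return ConservationTrack(scores)

    def test_separated_distributions_are_significant(self, intergenic_space):
        rng = np.random.default_rng(0)
        track = ConservationTrack(
            {"chr1": np.zeros(60_000), "chr2": np.zeros(40_000)}
        )
        cands = [GenomicInterval("chr1", 100 + 400 * i, 230 + 400 * i) for i in range(10)]
        for iv in cands:
            track.scores["chr1"][iv.start : iv.end] = 1.0
        verdict = conservation_significance(
            cands, track, intergenic_space, n_repeats=50, rng=rng
        )
        assert verdict.significant
        assert len(verdict.p_values) == 50  # the default repeat count
        assert max(verdict.p_values) < 1e-4

    def test_null_candidates_calibrate_near_nominal_size(self, intergenic_space):
        """Candidates drawn from background: ~5% of repeats give p < 0.05."""
        rng = np.random.default_rng(1)
        track = self._track(rng)
        lengths = [int(x) for x in rng.integers(80, 300, 40)]
        cands = sample_matched_intervals(lengths, intergenic_space, rng)
        verdict = conservation_significance(
            cands, track, intergenic_space, n_repeats=400, rng=rng
        )
        size = np.mean(np.array(verdict.p_values) < 0.05)
        assert 0.01 <= size <= 0.10

    def test_matched_sampling_preserves_lengths_and_space(self, intergenic_space):
        rng = np.random.default_rng(2)
        lengths = [100, 250, 5000]
        ivs = sample_matched_intervals(lengths, intergenic_space, rng)
        assert [len(iv) for iv in ivs] == lengths
        for iv in ivs:
            assert intergenic_space.contains(iv)

    def test_oversized_interval_raises(self, intergenic_space):
        with pytest.raises(ValueError, match="gap"):
            sample_matched_intervals([70_000], intergenic_space, np.random.default_rng(0))


class TestHomologyFilter:
    RECORDS = [
        HomologyRecord("t1", "s1", "snoRNA", 0.001, 96.0),
        HomologyRecord("t2", "s2", "snoRNA", 0.001, 94.9),
        HomologyRecord("t3", "s3", "miRNA", 0.02, 99.0),
        HomologyRecord("t4", "s4", "piRNA", 0.01, 95.0),
    ]

    def test_acceptance_rules(self):
        accepted, tallies = filter_homology_records(self.RECORDS)
        assert [r.transfrag_id for r in accepted] == ["t1", "t4"]
        assert tallies == {"snoRNA": 1, "piRNA": 1}

    def test_idempotent_and_order_independent(self):
        accepted, _ = filter_homology_records(self.RECORDS)
        again, _ = filter_homology_records(accepted)
        assert again == accepted
        rev, _ = filter_homology_records(self.RECORDS[::-1])
        assert sorted(r.transfrag_id for r in rev) == sorted(
            r.transfrag_id for r in accepted
        )


def _cand(tid, esc, npc):
    return SnacRNACandidate(
        transfrag_id=tid, region=GenomicInterval("chr1", 0, 100),
        category="intergenic", rpkm_by_cell={"ESC": esc, "NPC": npc},
        passes_threshold=True, max_orf_aa=0, coding_flag=False,
        mean_conservation=0.5, differential_score=0.0, log2_fold_change=0.0,
    )


class TestDifferentialRank:
    def test_equal_rpkm_scores_zero(self):
        (c,) = differential_rank([_cand("a", 5.0, 5.0)], "ESC", "NPC")
        assert c.differential_score == 0.0 and c.log2_fold_change == 0.0

    def test_planted_80_fold_locus_ranks_first(self):
        cands = [_cand("b", 20.0, 15.0), _cand("flag", 80.0, 1.0), _cand("c", 30.0, 28.0)]
        ranked = differential_rank(cands, "ESC", "NPC")
        assert ranked[0].transfrag_id == "flag"
        assert ranked[0].log2_fold_change > 6

    def test_stable_under_input_permutation(self):
        cands = [_cand(f"x{i}", float(i), 0.0) for i in range(6)]
        a = [c.transfrag_id for c in differential_rank(list(cands), "ESC", "NPC")]
        b = [c.transfrag_id for c in differential_rank(cands[::-1], "ESC", "NPC")]
        assert a == b == ["x5", "x4", "x3", "x2", "x1", "x0"]
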