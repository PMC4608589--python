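"""Alignment scores, the shuffle-null z statistic, and TMS-overlap counting."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from memfam.errors import DegenerateNullError
from memfam.paircompare import (
    AlignParams,
    align,
    alignment_score,
    count_aligned_tms,
    screen_families,
    shuffle_zscore,
    shuffled_copy,
)
from memfam.seqdata import FamilySet, ProteinRecord
from memfam.synthetic import random_protein
from memfam.topology import TmsAnnotation

from oracles import dp_global_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAlign:
    def test_self_alignment_equals_diagonal_sum(self, rng):
        matrix = substitution_matrices.load("BLOSUM62")
        seq = "".join(rng.choice(list(AA), size=40))
        result = align(seq, seq)
        assert result.score == sum(matrix[ch, ch] for ch in seq)

    def test_four_alanines(self):
        assert align("AAAA", "AAAA").score == 16.0

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list(AA), size=50))
        b = "".join(rng.choice(list(AA), size=60))
        assert align(a, b).score == align(b, a).score

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align("", "AAAA")

    def test_matches_exhaustive_dp_oracle_on_small_cases(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 13))
            m = int(rng.integers(1, 13))
            a = "".join(rng.choice(list(AA), size=n))
            b = "".join(rng.choice(list(AA), size=m))
            assert align(a, b).score == pytest.approx(dp_global_score(a, b)), (a, b)

    def test_path_with_gaps_covers_both_sequences_in_global_mode(self, rng):
        a = "".join(rng.choice(list(AA), size=30))
        b = "".join(rng.choice(list(AA), size=45))
        result = align(a, b)
        cols = list(result.path_with_gaps())
        assert [i for i, _ in cols if i is not None] == list(range(30))
        assert [j for _, j in cols if j is not None] == list(range(45))

    def test_gap_params_validation(self):
        with pytest.raises(ValueError):
            AlignParams(gap_open=1.0, gap_extend=2.0)


class TestShuffleZscore:
    def test_shuffles_preserve_composition_and_are_reproducible(self):
        b = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        s1 = shuffled_copy(b, seed=5, k=7)
        s2 = shuffled_copy(b, seed=5, k=7)
        assert s1 == s2
        assert sorted(s1) == sorted(b)
        assert shuffled_copy(b, seed=5, k=8) != s1

    def test_self_shuffle_null_is_centered(self):
        # a sequence against its own shuffles is one draw from the null
        a = random_protein(150, seed=9)
        zs = []
        for k in range(30):
            b = shuffled_copy(a.residues, seed=77, k=k)
            zs.append(shuffle_zscore(a.residues, b, n_shuffles=150, seed=k,
                                     keep_alignment=False).z_sd)
        assert abs(np.mean(zs)) < 0.5

    def test_identical_proteins_score_far_above_threshold(self):
        a = random_protein(200, seed=3)
        comp = shuffle_zscore(a, a, n_shuffles=500, seed=1, keep_alignment=False)
        assert comp.z_sd > 13.0

    def test_degenerate_null_raises(self):
        with pytest.raises(DegenerateNullError):
            shuffle_zscore("A" * 60, "A" * 60, n_shuffles=100, seed=0)

    def test_minimum_shuffle_count_enforced(self):
        a = random_protein(60, seed=1)
        with pytest.raises(ValueError):
            shuffle_zscore(a, a, n_shuffles=50)

    def test_result_carries_null_summary_and_seed(self):
        a = random_protein(80, seed=4)
        b = random_protein(80, seed=5)
        comp = shuffle_zscore(a, b, n_shuffles=120, seed=42)
        assert comp.null.n_shuffles == 120
        assert comp.null.seed == 42
        assert comp.null.null_sd > 0
        assert comp.z_sd == pytest.approx(
            (comp.raw_score - comp.null.null_mean) / comp.null.null_sd
        )


class TestFormatAlignment:
    def test_block_shows_names_score_and_identity_marks(self, rng):
        from memfam.paircompare import format_alignment

        a = ProteinRecord("Q1", "d", "".join(rng.choice(list(AA), size=40)))
        result = align(a.residues, a.residues)
        block = format_alignment(a, a.residues, result)
        assert "Q1" in block and f"score={result.score:.1f}" in block
        lines = block.splitlines()
        assert lines[1] == a.residues
        assert lines[2] == "|" * 40  # self-alignment: all identities
        assert lines[3] == a.residues


class TestCountAlignedTms:
    def test_hand_built_identity_alignment_counts_all_three(self):
        segments = [(0, 20), (30, 50), (60, 80)]
        ann_a = TmsAnnotation("A", segments)
        ann_b = TmsAnnotation("B", segments)
        pairs = [(i, i) for i in range(80)]
        assert count_aligned_tms(pairs, ann_a, ann_b) == 3

    def test_no_tms_gives_zero(self):
        pairs = [(i, i) for i in range(50)]
        assert count_aligned_tms(pairs, TmsAnnotation("A", []), TmsAnnotation("B", [])) == 0

    def test_overlap_minimum_gates_counting(self):
        ann_a = TmsAnnotation("A", [(0, 20)])
        ann_b = TmsAnnotation("B", [(0, 20)])
        pairs = [(i, i) for i in range(4)]  # below the 5-pair minimum
        assert count_aligned_tms(pairs, ann_a, ann_b) == 0
        pairs = [(i, i) for i in range(5)]
        assert count_aligned_tms(pairs, ann_a, ann_b) == 1

    def test_each_segment_used_at_most_once(self):
        # one segment of a overlapping two segments of b: only the bigger
        # overlap is counted
        ann_a = TmsAnnotation("A", [(0, 40)])
        ann_b = TmsAnnotation("B", [(0, 18), (22, 40)])
        pairs = [(i, i) for i in range(40)]
        assert count_aligned_tms(pairs, ann_a, ann_b) == 1

    def test_count_bounded_by_min_segment_count(self, small_truth):
        fam_a = small_truth.families[0]
        fam_b = small_truth.families[1]
        rec_a = fam_a.family.members[0]
        rec_b = fam_b.family.members[0]
        comp = shuffle_zscore(rec_a, rec_b, n_shuffles=100, seed=0)
        ann_a = fam_a.tms[rec_a.accession]
        ann_b = fam_b.tms[rec_b.accession]
        n = count_aligned_tms(comp, ann_a, ann_b)
        assert 0 <= n <= min(ann_a.n_tms, ann_b.n_tms)
        # related families with conserved architecture align most TMSs
        assert n >= 3


class TestScreenFamilies:
    def test_singleton_self_screen_returns_self_pair(self):
        rec = random_protein(120, seed=8, accession="S")
        fam = FamilySet("fam", [rec])
        results = screen_families(fam, fam, top_k=1, n_shuffles=150, seed=0)
        assert results[0].accession_a == "S"
        assert results[0].accession_b == "S"
        assert results[0].z_sd > 13.0

    def test_related_families_rank_above_threshold(self, small_truth):
        fam_a = small_truth.families[0].family
        fam_b = small_truth.families[1].family
        results = screen_families(fam_a, fam_b, top_k=2, n_shuffles=300, seed=5)
        assert results[0].z_sd >= 13.0
        assert results[0].z_sd >= results[-1].z_sd

    def test_deterministic_under_fixed_seed(self, small_truth):
        fam_a = small_truth.families[0].family
        fam_b = small_truth.families[2].family
        r1 = screen_families(fam_a, fam_b, top_k=1, n_shuffles=150, seed=9)
        r2 = screen_families(fam_a, fam_b, top_k=1, n_shuffles=150, seed=9)
        assert r1[0].accession_a == r2[0].accession_a
        assert r1[0].z_sd == r2[0].z_sd


class TestNullCalibration:
    def test_unrelated_pairs_are_approximately_standard_normal(self):
        zs = []
        for i in range(120):
            a = random_protein(180, seed=2000 + i)
            b = random_protein(180, seed=9000 + i)
            zs.append(
                shuffle_zscore(a, b, n_shuffles=150, seed=i, keep_alignment=False).z_sd
            )
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.35
        assert 0.7 < zs.std() < 1.3
        assert np.all(zs < 13.0)

    def test_median_z_decreases_along_divergence_ladder(self):
        from memfam.synthetic import related_pair

        medians = []
        for divergence in (0.1, 0.4, 0.7):
            zs = [
                shuffle_zscore(
                    *related_pair(divergence, seed=100 * k + int(divergence * 10)),
                    n_shuffles=150, seed=k, keep_alignment=False,
                ).z_sd
                for k in range(5)
            ]
            medians.append(np.median(zs))
        assert medians[0] > medians[1] > medians[2]
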