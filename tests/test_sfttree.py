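"""Bit-score matrices, distances, neighbor joining, and consensus trees."""

import math

import dendropy
import numpy as np
import pytest

from memfam.sfttree import (
    ScoreMatrix,
    bit_score,
    clade_supports,
    ensemble_consensus,
    is_monophyletic_in_unrooted,
    leaves_of,
    nj_tree,
    score_matrix,
    to_distances,
    triangle_violations,
)
from memfam.synthetic import random_protein

from oracles import random_additive_matrix, tree_path_distances


@pytest.fixture(scope="module")
def six_random():
    proteins = [random_protein(120, seed=70 + i, accession=f"P{i}") for i in range(6)]
    return proteins, score_matrix(proteins)


class TestScoreMatrix:
    def test_bit_transform(self):
        expected = (0.267 * 100 - math.log(0.041)) / math.log(2)
        assert bit_score(100.0) == pytest.approx(expected)

    def test_matrix_is_symmetric_with_maximal_diagonal(self, six_random):
        _, m = six_random
        assert np.allclose(m.bits, m.bits.T)
        for i in range(len(m.labels)):
            assert m.bits[i, i] >= m.bits[i].max() - 1e-9

    def test_entries_match_independent_recomputation(self, six_random):
        from memfam.paircompare import alignment_score

        proteins, m = six_random
        for i, j in ((0, 1), (2, 5), (3, 4)):
            raw = alignment_score(proteins[i], proteins[j])
            assert m.bits[i, j] == pytest.approx(bit_score(raw))

    def test_column_scores_reconstruct_raw_score(self, six_random):
        proteins, m = six_random
        for (i, j), cols in m.column_scores.items():
            raw = cols.sum() - m.gap_costs[(i, j)]
            assert bit_score(raw) == pytest.approx(m.bits[i, j])

    def test_identical_pair_dominates_its_rows(self):
        twin = random_protein(100, seed=99, accession="T0")
        proteins = [twin, random_protein(100, seed=98, accession="T1"),
                    random_protein(100, seed=97, accession="T2"),
                    type(twin)("T3", "copy", twin.residues)]
        m = score_matrix(proteins)
        off_diag = [m.bits[0, j] for j in range(1, 4)]
        assert m.bits[0, 3] == max(off_diag)


class TestDistances:
    def test_identical_pair_distance_zero(self):
        twin = random_protein(100, seed=1, accession="A")
        twin2 = type(twin)("B", "copy", twin.residues)
        extra = [random_protein(100, seed=5 + i, accession=f"C{i}") for i in range(2)]
        m = score_matrix([twin, twin2, *extra])
        d = to_distances(m)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(d) == 0.0)

    def test_unrelated_pair_distance_near_or_above_one(self):
        proteins = [random_protein(150, seed=200 + i, accession=f"U{i}") for i in range(4)]
        d = to_distances(score_matrix(proteins))
        off = d[np.triu_indices(4, k=1)]
        assert np.all(off > 0.9)

    def test_triangle_violations_reported_not_repaired(self, rng):
        d = np.array([
            [0.0, 0.1, 1.0],
            [0.1, 0.0, 0.1],
            [1.0, 0.1, 0.0],
        ])
        assert triangle_violations(d) > 0

    def test_non_positive_self_score_rejected(self):
        bits = np.array([[1.0, 0.2], [0.2, -1.0]])
        m = ScoreMatrix(labels=["a", "b"], family_tags=["", ""], bits=bits)
        with pytest.raises(ValueError):
            to_distances(m)


class TestNeighborJoining:
    def test_recovers_additive_four_leaf_tree_exactly(self):
        # ((A:1,B:2):1,(C:3,D:4)) as an additive matrix
        d = np.array([
            [0.0, 3.0, 5.0, 6.0],
            [3.0, 0.0, 6.0, 7.0],
            [5.0, 6.0, 0.0, 7.0],
            [6.0, 7.0, 7.0, 0.0],
        ])
        newick = nj_tree(d, ["A", "B", "C", "D"])
        paths = tree_path_distances(newick)
        labels = ["A", "B", "C", "D"]
        for i in range(4):
            for j in range(i + 1, 4):
                assert paths[frozenset((labels[i], labels[j]))] == pytest.approx(d[i, j])

    def test_recovers_random_additive_matrices(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            d = random_additive_matrix(rng, n)
            labels = [f"L{i}" for i in range(n)]
            paths = tree_path_distances(nj_tree(d, labels))
            for i in range(n):
                for j in range(i + 1, n):
                    assert paths[frozenset((labels[i], labels[j]))] == pytest.approx(
                        d[i, j], abs=1e-6
                    )

    def test_planted_families_form_clades(self, small_truth):
        proteins, tags = [], []
        for fam in small_truth.families:
            for rec in fam.family.members:
                proteins.append(rec)
                tags.append(fam.family.family_id)
        m = score_matrix(proteins, tags)
        newick = nj_tree(to_distances(m), m.labels)
        for fid in ("FAM1", "FAM2", "FAM3", "FAM4"):
            group = {p.accession for p, t in zip(proteins, tags) if t == fid}
            assert is_monophyletic_in_unrooted(newick, group), fid

    def test_non_finite_distances_rejected(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError):
            nj_tree(d, list("ABCD"))


class TestEnsembleConsensus:
    def test_identical_trees_give_that_tree_with_full_support(self):
        newick = "((A:1,B:1):1,(C:1,D:1):1);"
        supports = clade_supports([newick] * 10, ["A", "B", "C", "D"])
        assert supports[frozenset({"A", "B"})] == 1.0
        assert supports[frozenset({"C", "D"})] == 1.0

    def test_even_conflict_collapses_in_majority_rule(self):
        t1 = "((A:1,B:1):1,(C:1,D:1):1,E:1);"
        t2 = "((A:1,C:1):1,(B:1,D:1):1,E:1);"
        supports = clade_supports([t1, t2], ["A", "B", "C", "D", "E"])
        assert supports[frozenset({"A", "B"})] == 0.5
        assert supports[frozenset({"A", "C"})] == 0.5

    def test_bootstrap_consensus_keeps_leaves_and_planted_structure(self, small_truth):
        proteins, tags = [], []
        for fam in small_truth.families:
            for rec in fam.family.members:
                proteins.append(rec)
                tags.append(fam.family.family_id)
        m = score_matrix(proteins, tags)
        ensemble = ensemble_consensus(m, n_trees=30, seed=4)
        assert len(ensemble.trees) == 30
        assert leaves_of(ensemble.consensus) == set(m.labels)
        for fid in ("FAM1", "FAM2", "FAM3", "FAM4"):
            group = frozenset(
                p.accession for p, t in zip(proteins, tags) if t == fid
            )
            assert ensemble.supports.get(group, 0.0) >= 0.8, fid

    def test_ensemble_deterministic_under_seed(self, small_truth):
        proteins = [rec for fam in small_truth.families[:2] for rec in fam.family.members]
        m = score_matrix(proteins)
        e1 = ensemble_consensus(m, n_trees=10, seed=7)
        e2 = ensemble_consensus(m, n_trees=10, seed=7)
        assert e1.trees == e2.trees
        assert e1.consensus == e2.consensus

    def test_newick_round_trip_lossless_topology(self, small_truth):
        proteins = [rec for fam in small_truth.families[:2] for rec in fam.family.members]
        m = score_matrix(proteins)
        newick = nj_tree(to_distances(m), m.labels)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        again = tree.as_string(schema="newick").strip()
        assert leaves_of(again) == leaves_of(newick)
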