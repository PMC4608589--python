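"""Ground-truth generator: determinism, divergence control, truth consistency."""

import numpy as np
import pytest

from memfam.seqdata import pairwise_identity
from memfam.synthetic import (
    GeneratorConfig,
    SyntheticTruth,
    generate_superfamily,
    plant_motif,
    random_protein,
    related_pair,
    solve_site_rate,
    write_outputs,
)


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        cfg = GeneratorConfig(seed=77, members_per_family=3)
        out_a, out_b = tmp_path / "a", tmp_path / "b"
        write_outputs(generate_superfamily(cfg), out_a)
        write_outputs(generate_superfamily(cfg), out_b)
        for path in sorted(out_a.iterdir()):
            assert path.read_bytes() == (out_b / path.name).read_bytes(), path.name

    def test_different_seeds_differ(self):
        t1 = generate_superfamily(GeneratorConfig(seed=1, members_per_family=2))
        t2 = generate_superfamily(GeneratorConfig(seed=2, members_per_family=2))
        assert t1.root_sequence != t2.root_sequence

    def test_random_protein_reproducible(self):
        assert random_protein(100, seed=5).residues == random_protein(100, seed=5).residues


class TestDivergenceControl:
    @pytest.mark.parametrize("target", [0.1, 0.3, 0.5])
    def test_realized_within_family_divergence_near_target(self, target):
        truth = generate_superfamily(
            GeneratorConfig(
                seed=int(target * 100), members_per_family=4,
                within_family_divergence=target,
                between_family_divergence=max(target, 0.45),
                include_decoy=False, loop_del_prob=0.0,
            )
        )
        divergences = []
        for fam in truth.families:
            members = fam.family.members
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    divergences.append(
                        1 - pairwise_identity(members[i].residues, members[j].residues)
                    )
        assert abs(np.mean(divergences) - target) < 0.05

    def test_between_family_divergence_near_target(self):
        truth = generate_superfamily(
            GeneratorConfig(seed=9, members_per_family=3,
                            within_family_divergence=0.2,
                            between_family_divergence=0.45,
                            include_decoy=False, loop_del_prob=0.0)
        )
        cross = []
        f1 = truth.families[0].family.members
        f2 = truth.families[1].family.members
        for a in f1[:3]:
            for b in f2[:3]:
                cross.append(1 - pairwise_identity(a.residues, b.residues))
        assert abs(np.mean(cross) - 0.45) < 0.05

    def test_zero_divergence_members_identical_with_identical_halves(self, zero_div_truth):
        fam = zero_div_truth.families[0]
        first, second = fam.family.members
        assert first.residues == second.residues
        tms = fam.tms[first.accession].segments
        unit1 = first.residues[tms[0][0] : tms[2][1]]
        unit2 = first.residues[tms[3][0] : tms[5][1]]
        assert unit1 == unit2

    def test_related_pair_divergence_tracks_target(self):
        a, b = related_pair(0.3, seed=17)
        assert abs((1 - pairwise_identity(a.residues, b.residues)) - 0.3) < 0.06

    def test_site_rate_solver_inverts_expected_divergence(self):
        for c in (0.1, 0.3):
            for d in (0.1, 0.4, 0.6):
                p = solve_site_rate(d, c)
                realized = 2 * p * (1 - p) + p * p * (1 - c)
                assert realized == pytest.approx(d, abs=1e-9)
        # beyond saturation the solver caps at the maximizing rate
        assert solve_site_rate(0.9, 0.4) == pytest.approx(1 / 1.4)


class TestTruthConsistency:
    def test_degapped_msa_reproduces_fasta_exactly(self, small_truth):
        for fam in small_truth.all_families():
            for rec, row in zip(fam.family.members, fam.msa.members):
                assert rec.accession == row.accession
                assert row.residues.replace("-", "") == rec.residues

    def test_true_tms_intervals_are_hydrophobic(self, small_truth):
        from memfam.topology import KYTE_DOOLITTLE

        for fam in small_truth.families:
            for rec in fam.family.members:
                for start, end in fam.tms[rec.accession].segments:
                    segment = rec.residues[start:end]
                    mean_kd = np.mean([KYTE_DOOLITTLE[ch] for ch in segment])
                    assert mean_kd > 2.0

    def test_decoy_uses_two_tms_unit_geometry(self, small_truth):
        decoy = small_truth.decoy
        assert decoy.is_decoy
        for rec in decoy.family.members:
            assert decoy.tms[rec.accession].n_tms == 6

    def test_topology_variants_have_expected_tms_counts(self):
        for topology, expected in (("3+3", 6), ("3+3+1", 7), ("1+3+3", 7), ("3+3+2", 8)):
            truth = generate_superfamily(
                GeneratorConfig(seed=3, n_families=1, members_per_family=1,
                                topology=topology, include_decoy=False)
            )
            assert len(truth.root_tms) == expected, topology

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GeneratorConfig(within_family_divergence=0.95)
        with pytest.raises(ValueError):
            GeneratorConfig(within_family_divergence=0.5, between_family_divergence=0.3)


class TestPlantMotif:
    def test_planting_updates_sequence_row_and_truth(self):
        truth = generate_superfamily(
            GeneratorConfig(seed=61, n_families=1, members_per_family=4, include_decoy=False)
        )
        plant = plant_motif(truth, "FGX(K/R)XL", tms_index=2, fraction=1.0, seed=61)
        fam = truth.families[0]
        for rec, row in zip(fam.family.members, fam.msa.members):
            start, end = plant.placements[rec.accession]
            window = rec.residues[start:end]
            assert window[0] == "F" and window[1] == "G"
            assert window[3] in "KR" and window[5] == "L"
            assert row.residues.replace("-", "") == rec.residues
            seg_start, seg_end = fam.tms[rec.accession].segments[1]
            assert seg_start <= start and end <= seg_end

    def test_pattern_longer_than_tms_rejected(self):
        truth = generate_superfamily(
            GeneratorConfig(seed=62, n_families=1, members_per_family=1, include_decoy=False)
        )
        with pytest.raises(ValueError, match="longer"):
            plant_motif(truth, "X" * 30, tms_index=1, fraction=1.0)
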