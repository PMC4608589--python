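"""Hydropathy/amphipathicity profiles, TMS calling, and AveHAS averaging."""

import math

import numpy as np
import pytest

from memfam.seqdata import FamilySet, ProteinRecord
from memfam.synthetic import GeneratorConfig, generate_superfamily
from memfam.topology import (
    KYTE_DOOLITTLE,
    TmsAnnotation,
    TopologyParams,
    amphipathicity_profile,
    avehas,
    hydropathy_profile,
    predict_tms,
    read_tms_tsv,
    write_tms_tsv,
)


class TestHydropathyProfile:
    def test_homopolymer_equals_scale_value(self):
        for aa, expected in (("I", 4.5), ("R", -4.5)):
            profile = hydropathy_profile(aa * 60)
            assert np.allclose(profile, expected)

    def test_matches_brute_force_windowed_mean(self, rng):
        residues = "".join(rng.choice(list(KYTE_DOOLITTLE)[:20], size=200))
        params = TopologyParams()
        profile = hydropathy_profile(residues, params)
        half = params.hydropathy_window // 2
        for i in (0, 3, 50, 120, 199):
            window = residues[max(0, i - half) : i + half + 1]
            expected = sum(KYTE_DOOLITTLE[ch] for ch in window) / len(window)
            assert profile[i] == pytest.approx(expected)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_profile("MKT")

    def test_reversal_symmetry(self, rng):
        residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=150))
        fwd = hydropathy_profile(residues)
        rev = hydropathy_profile(residues[::-1])
        assert np.allclose(fwd, rev[::-1])


class TestAmphipathicityProfile:
    def test_zero_hydropathy_window_gives_zero(self):
        profile = amphipathicity_profile("X" * 60)
        assert np.allclose(profile, 0.0)

    def test_alternating_pattern_at_180_degrees_matches_vector_sum(self):
        # strictly alternating hydrophobic/hydrophilic with delta=180 puts
        # all contributions on one axis
        residues = "IR" * 30
        params = TopologyParams(helix_angle_deg=180.0)
        profile = amphipathicity_profile(residues, params)
        w = params.amphipathicity_window
        half = w // 2
        i = 30
        expected = abs(
            sum(
                KYTE_DOOLITTLE[residues[j]] * math.cos(j * math.pi)
                for j in range(i - half, i + half + 1)
            )
        ) / w
        assert profile[i] == pytest.approx(expected)

    def test_homopolymer_matches_geometric_series(self):
        residues = "L" * 80
        params = TopologyParams()
        profile = amphipathicity_profile(residues, params)
        w = params.amphipathicity_window
        delta = math.radians(params.helix_angle_deg)
        i = 40
        cos_sum = sum(math.cos(j * delta) for j in range(i - w // 2, i + w // 2 + 1))
        sin_sum = sum(math.sin(j * delta) for j in range(i - w // 2, i + w // 2 + 1))
        expected = KYTE_DOOLITTLE["L"] * math.hypot(cos_sum, sin_sum) / w
        assert profile[i] == pytest.approx(expected)


class TestPredictTms:
    def test_all_serine_has_no_segments(self):
        assert predict_tms("S" * 200).segments == []

    def test_recovers_planted_six_tms(self, small_truth):
        for fam in small_truth.families:
            for rec in fam.family.members:
                ann = predict_tms(rec)
                true_segments = small_truth.families[0].tms  # per-accession truth below
                true = fam.tms[rec.accession].segments
                assert ann.n_tms == 6
                for (ps, pe), (ts, te) in zip(ann.segments, true):
                    overlap = max(0, min(pe, te) - max(ps, ts))
                    assert overlap / (pe - ps) >= 0.8

    def test_seven_tms_for_3p3p1_topology(self):
        truth = generate_superfamily(
            GeneratorConfig(seed=31, n_families=1, members_per_family=3,
                            topology="3+3+1", include_decoy=False)
        )
        for rec in truth.families[0].family.members:
            assert predict_tms(rec).n_tms == 7

    def test_segments_respect_length_bounds(self, small_truth):
        params = TopologyParams()
        for fam in small_truth.families:
            for rec in fam.family.members:
                for start, end in predict_tms(rec, params).segments:
                    assert params.tms_min_len <= end - start <= params.tms_max_len


class TestTmsAnnotation:
    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            TmsAnnotation("X", [(0, 20), (15, 40)])

    def test_segment_index(self):
        ann = TmsAnnotation("X", [(5, 25), (40, 60)])
        assert ann.segment_index(5) == 0
        assert ann.segment_index(24) == 0
        assert ann.segment_index(30) is None
        assert ann.segment_index(59) == 1

    def test_tsv_round_trip(self, tmp_path):
        annotations = {
            "A1": TmsAnnotation("A1", [(5, 26), (40, 61)], source="imported"),
            "B2": TmsAnnotation("B2", [(0, 21)], source="predicted"),
        }
        path = tmp_path / "tms.tsv"
        write_tms_tsv(annotations, path)
        loaded = read_tms_tsv(path)
        assert loaded["A1"].segments == [(5, 26), (40, 61)]
        assert loaded["B2"].segments == [(0, 21)]


class TestAvehas:
    def test_identical_sequences_reduce_to_single_profile(self, rng):
        residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        msa = FamilySet(
            "fam", [ProteinRecord(f"S{i}", "d", residues) for i in range(4)]
        )
        profile = avehas(msa)
        assert profile.n_columns == 80
        assert np.allclose(profile.avg_hydropathy, hydropathy_profile(residues))
        assert np.allclose(profile.similarity, 1.0)
        assert np.all(profile.contributing_counts == 4)

    def test_single_contributor_column_convention(self):
        msa = FamilySet(
            "fam",
            [
                ProteinRecord("S1", "d", "A" * 40 + "W"),
                ProteinRecord("S2", "d", "A" * 40 + "-"),
            ],
        )
        profile = avehas(msa)
        assert profile.contributing_counts[-1] == 1
        assert profile.similarity[-1] == 0.0

    def test_two_sequence_similarity_matches_column_oracle(self, rng):
        from Bio.Align import substitution_matrices

        matrix = substitution_matrices.load("BLOSUM62")
        lo = float(np.array(matrix).min())
        a = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        b = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        msa = FamilySet("fam", [ProteinRecord("A", "d", a), ProteinRecord("B", "d", b)])
        profile = avehas(msa)
        for col in (0, 10, 59):
            hi = max(matrix[a[col], a[col]], matrix[b[col], b[col]])
            expected = max((matrix[a[col], b[col]] - lo) / (hi - lo), 0.0)
            assert profile.similarity[col] == pytest.approx(expected)

    def test_true_msa_profile_shows_conserved_tms_columns(self, small_truth):
        fam = small_truth.families[0]
        profile = avehas(fam.msa)
        assert profile.n_columns == len(fam.msa.members[0].residues)
        # TMS columns should be hydrophobic on average, loops not
        root_tms = small_truth.root_tms
        tms_cols = [c for s, e in root_tms for c in range(s, e)]
        loop_cols = [c for c in range(profile.n_columns) if c not in set(tms_cols)]
        assert profile.avg_hydropathy[tms_cols].mean() > 2.0
        assert profile.avg_hydropathy[loop_cols].mean() < 0.5

    def test_ragged_alignment_rejected(self):
        msa = FamilySet(
            "fam", [ProteinRecord("A", "d", "A" * 30), ProteinRecord("B", "d", "A" * 31)]
        )
        with pytest.raises(ValueError):
            avehas(msa)
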