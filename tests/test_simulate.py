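"""The synthetic-data generator: planted truth must be recoverable exactly."""

import numpy as np
import pytest

from helpers import hamming_fraction
from repeatburst.alphabet import revcomp
from repeatburst.errors import InputError, PlacementError, SaturationError
from repeatburst.simulate import (
    MirnaFamilyDef,
    TEFamilySpec,
    plant_copies_in_genome,
    simulate_cytometry,
    simulate_expression_matrix,
    simulate_mirna_families,
    simulate_te_copies,
)


class TestTECopies:
    def test_age_zero_copies_equal_master(self):
        fam = simulate_te_copies(TEFamilySpec("f", 1200, [0.0], [8], 0.5), seed=2)
        assert all(c == fam.master for c in fam.copies)

    def test_saturation_guard(self):
        with pytest.raises(SaturationError):
            TEFamilySpec("f", 1200, [1.0], [5], 0.8).validate()

    def test_mismatched_burst_lists(self):
        with pytest.raises(InputError):
            TEFamilySpec("f", 1200, [0.1, 0.2], [5], 0.1).validate()

    def test_within_young_burst_distance_matches_binomial_expectation(self, two_burst_family):
        # spec of the two-burst scenario: rate 0.3, young age 0.1 ->
        # expected pairwise distance ~ 2 * 0.3 * 0.1 = 0.06
        young = [c for c, a in zip(two_burst_family.copies, two_burst_family.ages) if a == 0.1]
        assert len(young) == 50
        dists = [
            hamming_fraction(young[i], young[j])
            for i in range(0, 20)
            for j in range(i + 1, 20)
        ]
        assert abs(float(np.mean(dists)) - 0.06) < 0.01

    def test_star_model_divergence_from_master(self):
        spec = TEFamilySpec("f", 2000, [1.0], [20], 0.05, model="star")
        fam = simulate_te_copies(spec, seed=9)
        div = np.mean([hamming_fraction(c, fam.master) for c in fam.copies])
        assert abs(div - 0.05) < 0.005  # substitutions always change the base

    def test_same_seed_reproducible_different_seed_not(self):
        spec = TEFamilySpec("f", 1000, [0.3], [4], 0.2)
        a = simulate_te_copies(spec, seed=1)
        b = simulate_te_copies(spec, seed=1)
        c = simulate_te_copies(spec, seed=2)
        assert a.copies == b.copies and a.master == b.master
        assert a.copies != c.copies


class TestPlanting:
    def test_zero_copies_exact_background(self):
        genome, truth = plant_copies_in_genome(10000, [], seed=0)
        assert len(next(iter(genome.values()))) == 10000
        assert truth.copy_coordinates == []

    def test_round_trip_extraction(self, planted_single_family):
        fam, genome, truth = planted_single_family
        seq = genome["contig_1"]
        for c in truth.copy_coordinates:
            piece = seq[c.start:c.end]
            if c.strand == "-":
                piece = revcomp(piece)
            assert piece == fam.master

    def test_occupancy_precondition(self):
        with pytest.raises(PlacementError):
            plant_copies_in_genome(100000, ["A" * 1000] * 60, seed=0)

    def test_seed_changes_placement(self):
        copies = ["ACGT" * 300] * 5
        g1, t1 = plant_copies_in_genome(50000, copies, seed=1)
        g2, t2 = plant_copies_in_genome(50000, copies, seed=2)
        assert [c.start for c in t1.copy_coordinates] != [c.start for c in t2.copy_coordinates]


class TestMirnaSim:
    def test_zero_mutation_copies_verbatim(self):
        fams = [MirnaFamilyDef("f1", "AAAGUGCUUUCUGUUUUGGGCG", 5, per_copy_mutations=0)]
        sim = simulate_mirna_families(fams, seed=0)
        mature_dna = "AAAGUGCUUUCUGUUUUGGGCG".replace("U", "T")
        assert len(sim.precursors) == 5
        assert all(mature_dna in seq for _, seq in sim.precursors)

    def test_default_copy_numbers(self):
        sim = simulate_mirna_families(seed=3)
        assert sim.truth_counts == {"mir-427-like": 155, "mir-93b-like": 66}
        assert len(sim.precursors) == 221

    def test_mutations_spare_the_seed(self):
        sim = simulate_mirna_families(seed=1)
        for pid, seq in sim.precursors:
            assert "AAGTGC" in seq

    def test_short_mature_rejected(self):
        with pytest.raises(InputError):
            simulate_mirna_families(
                [MirnaFamilyDef("bad", "AAAGUGCUUU", 3)], seed=0
            )


class TestExpressionSim:
    def test_degenerate_limit_uniform(self):
        sim = simulate_expression_matrix(50, 5, 0.3, fold_effect=1.0, dispersion=0.0, seed=0)
        assert np.allclose(sim.matrix.values, sim.matrix.values[:, [0]])

    def test_specific_count_exact(self):
        sim = simulate_expression_matrix(1000, 9, 0.2, seed=11)
        assert len(sim.specific_gene_ids) == 200
        assert len(sim.broad_gene_ids) == 800

    def test_single_tissue_rejected(self):
        with pytest.raises(InputError):
            simulate_expression_matrix(10, 1, 0.2)

    def test_all_values_positive(self):
        sim = simulate_expression_matrix(200, 6, 0.5, seed=4)
        assert (sim.matrix.values > 0).all()


class TestCytometrySim:
    def test_identity_when_equal(self):
        sample, ref = simulate_cytometry(26.9, 26.9, 13746.0, noise_sd=0.0)
        assert sample == ref

    def test_ratio_arithmetic(self):
        sample, _ = simulate_cytometry(39.64, 26.9, 13746.0, noise_sd=0.0)
        assert sample == pytest.approx(20255, abs=5)

    def test_negative_peak_rejected(self):
        with pytest.raises(InputError):
            simulate_cytometry(39.64, 26.9, -1.0)
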