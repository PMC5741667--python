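"""Distance matrices, burst-mode detection and domain retention."""

import numpy as np
import pytest

from helpers import hamming_fraction
from repeatburst.errors import InputError, InsufficientDataError
from repeatburst.landscape import detect_bursts, domain_retention, pairwise_distances
from repeatburst.simulate import (
    MYB_LIKE_PEPTIDE,
    RT_LIKE_PEPTIDE,
    TEFamilySpec,
    simulate_te_copies,
)


class TestPairwiseDistances:
    def test_identical_copies_zero(self):
        dm = pairwise_distances(["ACGT" * 300] * 3)
        assert np.allclose(dm.values, 0.0)
        assert dm.kept_mask.all()

    def test_hamming_oracle_thirty_mismatches(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 1000))
        b = list(a)
        pos = rng.choice(1000, 30, replace=False)
        for p in pos:
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        dm = pairwise_distances([a, b, a])
        assert dm.values[0, 1] == pytest.approx(0.030, abs=1e-12)

    def test_distances_equal_hamming_on_indel_free_copies(self, two_burst_family):
        copies = two_burst_family.copies[:10] + two_burst_family.copies[-10:]
        dm = pairwise_distances(copies)
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                assert dm.values[i, j] == pytest.approx(
                    hamming_fraction(copies[i], copies[j]), abs=1e-12
                )

    def test_truncated_copy_dropped(self):
        fam = simulate_te_copies(TEFamilySpec("f", 2000, [0.3], [6], 0.1), seed=3)
        copies = list(fam.copies)
        copies[2] = copies[2][:800]  # 40% of full length
        dm = pairwise_distances(copies, min_mutual_coverage=0.8)
        assert not dm.kept_mask[2]
        assert dm.kept_mask.sum() == 5

    def test_too_few_copies(self):
        with pytest.raises(InsufficientDataError):
            pairwise_distances(["ACGT" * 300] * 2)

    def test_matrix_symmetry_zero_diagonal(self, two_burst_family):
        dm = pairwise_distances(two_burst_family.copies[:8])
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)


class TestDetectBursts:
    def test_gaussian_single_mode(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rep = detect_bursts(rng.normal(0.2, 0.02, 1500), seed=seed)
            ok += rep.n_modes == 1
        assert ok >= 19

    def test_well_separated_two_modes(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            d = np.concatenate(
                [rng.normal(0.1, 0.02, 800), rng.normal(0.1 + 4 * 0.02, 0.02, 800)]
            )
            rep = detect_bursts(d, seed=seed)
            ok += rep.n_modes == 2
        assert ok >= 19

    def test_constant_distances_single_mode(self):
        rep = detect_bursts(np.full(100, 0.25))
        assert rep.n_modes == 1

    def test_weights_sum_to_one_and_means_sorted(self):
        rng = np.random.default_rng(0)
        d = np.concatenate([rng.normal(0.05, 0.01, 500), rng.normal(0.3, 0.02, 500)])
        rep = detect_bursts(d)
        assert sum(rep.mode_weights) == pytest.approx(1.0, abs=1e-9)
        assert rep.mode_means == sorted(rep.mode_means)
        assert set(rep.model_scores) == {1, 2, 3}

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            detect_bursts(np.linspace(0, 1, 29))


@pytest.fixture(scope="module")
def intact_copies():
    spec = TEFamilySpec("h", 2000, [0.0], [10], 0.1, has_domain=True)
    return simulate_te_copies(spec, seed=1).copies


class TestDomainRetention:
    def test_intact_orf_full_retention(self, intact_copies):
        ret = domain_retention(intact_copies, [("Myb", MYB_LIKE_PEPTIDE)])
        assert ret["Myb"] == 1.0

    def test_frameshift_fraction_deterministic(self, intact_copies):
        disrupted = [c[:990] + "A" + c[990:] for c in intact_copies[:4]]
        ret = domain_retention(
            intact_copies[:6] + disrupted, [("Myb", MYB_LIKE_PEPTIDE)]
        )
        assert ret["Myb"] == pytest.approx(0.6)

    def test_absent_domain_zero(self, intact_copies):
        ret = domain_retention(intact_copies, [("RT", RT_LIKE_PEPTIDE)])
        assert ret["RT"] == 0.0

    def test_short_profile_rejected(self, intact_copies):
        with pytest.raises(InputError):
            domain_retention(intact_copies, [("tiny", "MKGPWTREED")])

    def test_empty_profile_list_rejected(self, intact_copies):
        with pytest.raises(InputError):
            domain_retention(intact_copies, [])
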