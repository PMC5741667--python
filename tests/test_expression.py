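"""TPM normalisation, tau scoring and group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repeatburst.errors import (
    DegenerateColumnError,
    InputError,
    InsufficientDataError,
    UndefinedTauError,
)
from repeatburst.expression import (
    compare_tau_groups,
    counts_to_tpm,
    tau_score,
    tau_table,
)
from repeatburst.simulate import simulate_expression_matrix


class TestCountsToTpm:
    def test_symmetric_genes(self):
        counts = pd.DataFrame({"t1": [10, 10]}, index=["g1", "g2"])
        tpm = counts_to_tpm(counts, pd.Series([500, 500], index=["g1", "g2"]))
        assert np.allclose(tpm["t1"], [500000.0, 500000.0])

    def test_length_normalisation(self):
        counts = pd.DataFrame({"t1": [10, 10]}, index=["g1", "g2"])
        tpm = counts_to_tpm(counts, pd.Series([1000, 2000], index=["g1", "g2"]))
        assert tpm["t1"].values == pytest.approx([666666.67, 333333.33], abs=0.01)

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 500, (30, 4)),
            index=[f"g{i}" for i in range(30)],
            columns=list("ABCD"),
        )
        counts.iloc[0] += 1  # avoid an all-zero column
        tpm = counts_to_tpm(counts, pd.Series(rng.integers(200, 5000, 30), index=counts.index))
        assert np.allclose(tpm.sum(axis=0), 1e6, atol=1e-3)

    def test_zero_column_rejected(self):
        counts = pd.DataFrame({"t1": [5, 5], "t2": [0, 0]}, index=["g1", "g2"])
        with pytest.raises(DegenerateColumnError):
            counts_to_tpm(counts, pd.Series([100, 100], index=["g1", "g2"]))


class TestTauScore:
    def test_uniform_expression_is_zero(self):
        assert tau_score([7.5] * 9) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_single_tissue_limit(self, n):
        x = [0.0] * n
        x[0] = 42.0
        assert tau_score(x) == pytest.approx(1 - 1 / n, abs=1e-15)

    def test_hand_computed_example(self):
        assert tau_score([10, 5, 0, 0, 5]) == pytest.approx(0.6, abs=1e-12)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedTauError):
            tau_score([0.0, 0.0, 0.0])

    def test_yanai_variant(self):
        # excludes the max, divides by n-1: one-tissue vector scores exactly 1
        x = [0.0, 0.0, 9.0]
        assert tau_score(x, method="yanai") == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1e4), min_size=2, max_size=12),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, xs, scale):
        assert tau_score([x * scale for x in xs]) == pytest.approx(
            tau_score(xs), abs=1e-9
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e3), min_size=3, max_size=10))
    def test_concentration_increases_tau(self, xs):
        # moving all mass into the argmax tissue can only raise tau
        conc = [0.0] * len(xs)
        conc[int(np.argmax(xs))] = sum(xs)
        assert tau_score(conc) >= tau_score(xs) - 1e-12


class TestTauTable:
    def test_floor_exclusion(self):
        expr = pd.DataFrame(
            {"t1": [100.0, 0.5], "t2": [50.0, 0.2]}, index=["hi", "lo"]
        )
        res = tau_table(expr, min_tpm=1.0)
        assert res.excluded_genes == ["lo"]
        assert list(res.tau.index) == ["hi"]
        assert res.max_tissue["hi"] == "t1"

    def test_replicate_averaging(self):
        expr = pd.DataFrame(
            {"a1": [4.0], "a2": [6.0], "b1": [10.0]}, index=["g"]
        )
        res = tau_table(expr, replicates={"a": ["a1", "a2"], "b": ["b1"]})
        assert res.tau["g"] == pytest.approx(1 - (0.5 + 1.0) / 2)


class TestCompareGroups:
    def test_identical_groups_null(self):
        a = np.full(10, 0.5)
        out = compare_tau_groups(a, a)
        assert out["rank_statistic"] == pytest.approx(50.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_extreme_separation(self):
        out = compare_tau_groups([0.9] * 5, [0.1] * 5)
        assert out["median_a"] - out["median_b"] == pytest.approx(0.8)
        assert out["p_value"] < 0.01

    def test_group_size_floor(self):
        with pytest.raises(InsufficientDataError):
            compare_tau_groups([0.5] * 4, [0.5] * 10)

    def test_planted_specific_genes_score_higher(self):
        sim = simulate_expression_matrix(600, 9, 0.2, fold_effect=8.0,
                                         dispersion=0.3, seed=13)
        res = tau_table(sim.matrix, min_tpm=0.0)
        spec = res.tau[sim.specific_gene_ids]
        broad = res.tau[sim.broad_gene_ids]
        out = compare_tau_groups(spec, broad)
        assert out["median_a"] > out["median_b"]
        assert out["p_value"] < 1e-10
        # rank separation: fraction of (specific, broad) pairs correctly ordered
        auc = out["rank_statistic"] / (len(spec) * len(broad))
        assert auc >= 0.95
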