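from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import monomethir as mm


class TestHomaIr:
    def test_direct_formula_and_boundary(self):
        assert mm.homa_ir(90, 9) == pytest.approx(2.0)
        assert mm.stratify(2.0) == "IR"  # boundary value is IR
        assert mm.homa_ir(81, 5) == pytest.approx(1.0)
        assert mm.stratify(1.0) == "IS"

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm.homa_ir(90, 0)

    def test_vectorized(self):
        out = mm.homa_ir([90, 81], [9, 5])
        np.testing.assert_allclose(out, [2.0, 1.0])
        assert list(mm.stratify(out)) == ["IR", "IS"]


def _mw_enumeration_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating every label assignment."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_stat(idx):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, len(x) * len(y) - u1)

    observed = u_stat(range(n1))
    count = sum(
        u_stat(c) <= observed for c in combinations(range(len(pooled)), n1)
    )
    return count / len(list(combinations(range(len(pooled)), n1)))


class TestMannWhitney:
    def test_textbook_exact_case(self):
        u, p = mm.mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_vectors_give_p_one(self):
        _, p = mm.mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (3, 8, 3)])
    def test_exact_p_matches_enumeration_for_small_samples(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.permutation(np.arange(n1 + n2, dtype=float))[:n1]
        y = np.setdiff1d(np.arange(n1 + n2, dtype=float), x)
        _, p = mm.mann_whitney(x, y)
        assert p == pytest.approx(_mw_enumeration_oracle(x, y), abs=1e-12)

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            mm.mann_whitney([1, 2], [3, 4, 5])


class TestSpearman:
    def test_perfect_monotone(self):
        r, _ = mm.spearman([1, 2, 3, 4], [10, 20, 25, 70])
        assert r == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mm.spearman([1, 1, 1], [1, 2, 3])


class TestEnrichment:
    def test_two_cell_chi_square_closed_form(self):
        """66 observed vs 41 expected of 123: χ² = 625/41 + 625/82."""
        chi2, p = mm.goodness_of_fit_chi2(66, 41, 123)
        assert chi2 == pytest.approx(625 / 41 + 625 / 82, abs=1e-9)
        assert p < 0.05

    def test_observed_equal_expected_gives_zero(self):
        chi2, p = mm.goodness_of_fit_chi2(41, 41, 123)
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_family_counts_sum_and_direction(self, cohort):
        planted = cohort.truth.index[cohort.truth["is_planted_dml"]]
        out = mm.region_enrichment(planted, cohort.annotation, family="gene_region")
        assert out["observed"].sum() == len(planted)
        body = out.set_index("category").loc["Body"]
        assert body["direction"] == "enriched"  # planted DMLs are body-heavy
        expected = len(planted) * (
            (cohort.annotation.table["gene_region"] == "Body").mean()
        )
        assert body["expected"] == pytest.approx(expected)

    def test_bonferroni_uses_family_size(self, cohort):
        planted = cohort.truth.index[cohort.truth["is_planted_dml"]]
        out = mm.region_enrichment(planted, cohort.annotation, family="gene_region")
        row = out.iloc[0]
        assert row["p_bonf"] == pytest.approx(min(1.0, row["p"] * len(out)))


class TestManhattanCluster:
    def test_l1_distance_arithmetic(self):
        df = pd.DataFrame({"s1": [0.0, 0.5], "s2": [0.1, 0.6]}, index=["cg1", "cg2"])
        Z, leaves = mm.manhattan_cluster(df)
        assert Z[0, 2] == pytest.approx(0.2)
        assert set(leaves) == {"s1", "s2"}

    def test_duplicate_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(1)
        col = rng.random(10)
        df = pd.DataFrame({"a": col, "b": col, "c": col + 0.3}, index=range(10))
        Z, _ = mm.manhattan_cluster(df)
        assert Z[0, 2] == 0.0 and {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_probe_order_invariance(self, cohort):
        planted = cohort.truth.index[cohort.truth["is_planted_dml"]][:50]
        block = cohort.beta.values.loc[planted]
        Z1, l1 = mm.manhattan_cluster(block)
        Z2, l2 = mm.manhattan_cluster(block.iloc[::-1])
        np.testing.assert_allclose(Z1, Z2)
        assert l1 == l2

    def test_planted_groups_separate_at_two_cluster_cut(self, cohort):
        planted = cohort.truth.index[cohort.truth["is_planted_dml"]][:100]
        Z, _ = mm.manhattan_cluster(cohort.beta.values.loc[planted])
        purity = mm.two_cluster_purity(Z, cohort.beta.sample_ids, cohort.samples.groups)
        assert purity >= 0.90

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            mm.manhattan_cluster(pd.DataFrame({"s1": [0.1, 0.2]}))


class TestPower:
    def test_noncentral_t_iteration(self):
        """δ=0.10, sd=0.08 needs 12 per group for 80% power at α=0.05
        (power is 0.796 at n=11, 0.833 at n=12)."""
        assert mm.power_sample_size(0.10, 0.08) == 12

    def test_huge_effect_needs_minimum_n(self):
        assert mm.power_sample_size(5.0, 0.01) == 2

    def test_halving_delta_roughly_quadruples_n(self):
        n1 = mm.power_sample_size(0.10, 0.08)
        n2 = mm.power_sample_size(0.05, 0.08)
        assert 3.3 <= n2 / n1 <= 4.7

    def test_invalid_power_rejected(self):
        with pytest.raises(ValueError):
            mm.power_sample_size(0.1, 0.1, power=1.0)


class TestGeneSetFisher:
    def test_enriched_set_detected(self):
        query = [f"G{i}" for i in range(10)]
        background = [f"G{i}" for i in range(200)]
        sets = {
            "hit": query[:8] + ["G100", "G101"],
            "miss": [f"G{i}" for i in range(150, 170)],
        }
        out = mm.gene_set_fisher(query, background, sets).set_index("gene_set")
        assert out.loc["hit", "p"] < 0.001 < out.loc["miss", "p"]
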