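from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import monomethir as mm
from monomethir.dml import D0_CAP, ShrinkageEstimate


def _matrix(rows, samples):
    probes = [f"cg{i}" for i in range(len(rows))]
    return mm.BetaMatrix(pd.DataFrame(rows, index=probes, columns=samples))


def _groups(samples):
    return pd.Series(["IR" if s.startswith("IR") else "IS" for s in samples],
                     index=samples)


SAMPLES_3_3 = ["IS1", "IS2", "IS3", "IR1", "IR2", "IR3"]


class TestGroupStats:
    def test_hand_computed_three_vs_three(self):
        is_vals = [0.60, 0.70, 0.80]
        ir_vals = [0.40, 0.50, 0.60]
        beta = _matrix([is_vals + ir_vals], SAMPLES_3_3)
        st = mm.group_stats(beta, _groups(SAMPLES_3_3))
        # hand arithmetic: means 0.7 and 0.5, each group variance 0.01
        assert st.loc["cg0", "mean_is"] == pytest.approx(0.70)
        assert st.loc["cg0", "mean_ir"] == pytest.approx(0.50)
        assert st.loc["cg0", "delta"] == pytest.approx(-0.20)
        assert st.loc["cg0", "s_sq"] == pytest.approx((0.02 + 0.02) / 4)
        assert st.loc["cg0", "d"] == 4

    def test_printed_mean_pair_gives_minus_point_ten(self):
        """Group means 0.69 (IS) vs 0.59 (IR) yield δ = −0.10."""
        beta = _matrix([[0.68, 0.69, 0.70, 0.58, 0.59, 0.60]], SAMPLES_3_3)
        st = mm.group_stats(beta, _groups(SAMPLES_3_3))
        assert st.loc["cg0", "delta"] == pytest.approx(-0.10)

    def test_identical_groups_give_zero_delta_and_t(self):
        beta = _matrix([[0.3, 0.4, 0.5, 0.3, 0.4, 0.5]], SAMPLES_3_3)
        st = mm.group_stats(beta, _groups(SAMPLES_3_3))
        t = mm.moderated_t(st, None)
        assert st.loc["cg0", "delta"] == 0.0
        assert t.loc["cg0"] == 0.0

    def test_missing_values_adjust_degrees_of_freedom(self):
        row = [0.6, 0.7, np.nan, 0.4, 0.5, 0.6]
        beta = _matrix([row], SAMPLES_3_3)
        st = mm.group_stats(beta, _groups(SAMPLES_3_3))
        assert st.loc["cg0", "n_is"] == 2
        assert st.loc["cg0", "d"] == 3

    def test_probe_with_one_usable_value_marked_unusable(self):
        row = [0.6, np.nan, np.nan, 0.4, 0.5, 0.6]
        beta = _matrix([row, [0.1] * 6], SAMPLES_3_3)
        st = mm.group_stats(beta, _groups(SAMPLES_3_3))
        assert not st.loc["cg0", "usable"]
        assert st.loc["cg1", "usable"]


class TestShrinkage:
    def test_recovers_known_inverse_chisquare_prior(self):
        rng = np.random.default_rng(0)
        d0, s0_sq, d = 4.0, 0.01, 35
        sigma2 = d0 * s0_sq / rng.chisquare(d0, 10000)
        s_sq = sigma2 * rng.chisquare(d, 10000) / d
        est = mm.estimate_shrinkage(s_sq, d)
        assert 3.0 <= est.d0 <= 5.0
        assert abs(est.s0_sq - s0_sq) / s0_sq <= 0.20

    def test_constant_variances_hit_cap_and_moderated_equals_ordinary_t(self):
        s_sq = np.full(200, 0.01)
        est = mm.estimate_shrinkage(s_sq, 10)
        assert est.capped
        stats = pd.DataFrame(
            {"delta": [0.1], "s_sq": [0.01], "d": [10.0], "n_is": [6], "n_ir": [6]},
            index=["cg0"],
        )
        t_mod = mm.moderated_t(stats, est)
        t_ord = mm.moderated_t(stats, None)
        assert t_mod.loc["cg0"] == pytest.approx(t_ord.loc["cg0"], abs=1e-12)

    def test_too_few_probes_rejected(self):
        with pytest.raises(ValueError, match="probes"):
            mm.estimate_shrinkage([0.01, 0.02], 10)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            mm.estimate_shrinkage(np.zeros(100), 10)


class TestModeratedT:
    def test_matches_direct_formula(self):
        est = ShrinkageEstimate(d0=4.0, s0_sq=0.01, d=10.0)
        stats = pd.DataFrame(
            {"delta": [0.12], "s_sq": [0.02], "d": [10.0], "n_is": [7], "n_ir": [5]},
            index=["cg0"],
        )
        s_tilde = (4.0 * 0.01 + 10.0 * 0.02) / (4.0 + 10.0)
        expected = 0.12 / np.sqrt(s_tilde * (1 / 7 + 1 / 5))
        assert mm.moderated_t(stats, est).loc["cg0"] == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("scale", [1.0, 1.5, 3.0, 10.0])
    def test_monotone_in_effect_size(self, scale):
        est = ShrinkageEstimate(d0=4.0, s0_sq=0.01, d=10.0)
        base = pd.DataFrame(
            {"delta": [0.05], "s_sq": [0.02], "d": [10.0], "n_is": [7], "n_ir": [5]})
        bigger = base.assign(delta=base["delta"] * scale)
        assert abs(mm.moderated_t(bigger, est).iloc[0]) >= abs(
            mm.moderated_t(base, est).iloc[0]
        )


class TestPermutation:
    def test_unequal_groups_separable_probe_hits_minimum_p(self):
        """5v3 exhaustive: 56 label arrangements; a cleanly separated probe is
        strictly largest so p = (1+1)/(1+56), with the observed arrangement
        counted in the null."""
        samples = ["IS1", "IS2", "IS3", "IS4", "IS5", "IR1", "IR2", "IR3"]
        row = [0.81, 0.80, 0.82, 0.83, 0.79, 0.20, 0.22, 0.21]
        beta = _matrix([row], samples)
        res = mm.permutation_pvalues(
            beta, _groups(samples), B="exhaustive", pool=False, shrinkage_mode="none"
        )
        assert res["p_perm"].iloc[0] == pytest.approx(2.0 / 57.0, abs=1e-15)

    def test_exhaustive_matches_enumeration_oracle(self):
        """Full-array equality against an independent oracle that enumerates
        every 4v4 label assignment and recomputes the pooled t from scratch."""
        rng = np.random.default_rng(21)
        samples = ["IS1", "IS2", "IS3", "IS4", "IR1", "IR2", "IR3", "IR4"]
        vals = rng.uniform(0.2, 0.8, size=(60, 8))
        beta = _matrix(list(vals), samples)
        res = mm.permutation_pvalues(
            beta, _groups(samples), B="exhaustive", pool=False, shrinkage_mode="none"
        )

        def pooled_t(x, y):
            nx, ny = len(x), len(y)
            sp = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
            return (np.mean(y) - np.mean(x)) / np.sqrt(sp * (1 / nx + 1 / ny))

        arrangements = list(combinations(range(8), 4))
        for j, row in enumerate(vals):
            t_obs = abs(pooled_t(row[:4], row[4:]))
            count = sum(
                abs(pooled_t(row[list(c)], row[[i for i in range(8) if i not in c]]))
                >= t_obs
                for c in arrangements
            )
            expected = (1 + count) / (1 + len(arrangements))
            assert res["p_perm"].iloc[j] == pytest.approx(expected, abs=1e-12)

    def test_identical_group_blocks_give_p_one(self):
        samples = SAMPLES_3_3
        rng = np.random.default_rng(3)
        half = rng.uniform(0.2, 0.8, size=(20, 3))
        beta = _matrix(list(np.hstack([half, half])), samples)
        res = mm.permutation_pvalues(
            beta, _groups(samples), B="exhaustive", pool=False, shrinkage_mode="none"
        )
        assert (res["p_perm"] == 1.0).all()

    def test_null_pvalues_are_calibrated(self):
        """Global-null cohort: pooled permutation p-values are approximately
        uniform (tail mass near nominal)."""
        cohort = mm.simulate_cohort(n_probes=2000, n_dml=0, delta=0.0, seed=17)
        res = mm.permutation_pvalues(cohort.beta, cohort.samples.groups, B=150, seed=17)
        frac20 = (res["p_perm"] < 0.20).mean()
        assert 0.16 <= frac20 <= 0.24

    def test_qvalues_monotone_in_statistic(self, cohort_records):
        rec = cohort_records.dropna(subset=["t_mod", "q_perm"])
        ordered = rec.sort_values("t_mod", key=lambda s: s.abs(), ascending=False)
        q = ordered["q_perm"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_small_B_rejected(self, cohort):
        with pytest.raises(ValueError, match="B"):
            mm.permutation_pvalues(cohort.beta, cohort.samples.groups, B=10, seed=1)

    def test_exhaustive_rejected_for_large_cohorts(self, cohort):
        with pytest.raises(ValueError, match="exhaustive"):
            mm.permutation_pvalues(cohort.beta, cohort.samples.groups, B="exhaustive")


class TestCallDmls:
    def _records(self, deltas, ps):
        n = len(deltas)
        return pd.DataFrame(
            {"delta": deltas, "p_perm": ps,
             "mean_is": [0.5] * n, "mean_ir": [0.5] * n},
            index=[f"cg{i}" for i in range(n)],
        )

    def test_boundary_delta_inclusive(self):
        rec, summary = mm.call_dmls(self._records([-0.10], [0.01]))
        assert rec["is_dml"].iloc[0]
        assert summary["n_dml"] == 1

    def test_flagged_probe_excluded(self):
        records = self._records([-0.2], [0.001])
        records["flag_snp_pattern"] = True
        rec, _ = mm.call_dmls(records)
        assert not rec["is_dml"].iloc[0]

    def test_thresholds_validated(self):
        with pytest.raises(ValueError):
            mm.call_dmls(self._records([0.2], [0.01]), p_threshold=1.5)

    def test_dml_set_shrinks_as_thresholds_tighten(self, cohort_records):
        loose, _ = mm.call_dmls(cohort_records, p_threshold=0.05, delta_threshold=0.10)
        tight_p, _ = mm.call_dmls(cohort_records, p_threshold=0.01, delta_threshold=0.10)
        tight_d, _ = mm.call_dmls(cohort_records, p_threshold=0.05, delta_threshold=0.14)
        loose_set = set(loose.index[loose["is_dml"]])
        assert set(tight_p.index[tight_p["is_dml"]]) <= loose_set
        assert set(tight_d.index[tight_d["is_dml"]]) <= loose_set

    def test_direction_summary_fraction(self):
        """106 of 123 loci with δ < 0 reports 86.2% hypomethylated in IR."""
        deltas = [-0.15] * 106 + [0.15] * 17
        out = mm.direction_summary(deltas)
        assert out == {
            "n_direction": 123, "n_hypo_ir": 106, "n_hyper_ir": 17,
            "pct_hypo_ir": 86.2,
        }
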