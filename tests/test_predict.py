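import numpy as np
import pandas as pd
import pytest

import monomethir as mm
from monomethir.predict import LogisticModel


def _logistic_data(b0, b1, n, seed, x_range=(0.2, 1.0)):
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, n)
    p = 1.0 / (1.0 + np.exp(-(b0 + b1 * x)))
    y = (rng.random(n) < p).astype(int)
    X = pd.DataFrame({"cpg": x}, index=[f"s{i}" for i in range(n)])
    return X, pd.Series(y, index=X.index)


class TestSelectCandidates:
    def test_separable_probe_selected_among_nulls(self):
        rng = np.random.default_rng(1)
        probes = [f"cg{i}" for i in range(11)]
        samples = [f"IS{i}" for i in range(12)] + [f"IR{i}" for i in range(12)]
        vals = rng.uniform(0.3, 0.7, size=(11, 24))
        vals[0, :12] = rng.uniform(0.7, 0.9, 12)  # IS high
        vals[0, 12:] = rng.uniform(0.1, 0.3, 12)  # IR low: fully separable
        beta = mm.BetaMatrix(pd.DataFrame(vals, index=probes, columns=samples))
        groups = pd.Series(["IS"] * 12 + ["IR"] * 12, index=samples)
        selected = mm.select_candidates(beta, groups)
        assert selected == ["cg0"]

    def test_threshold_one_selects_everything(self, cohort):
        sub = cohort.beta.subset(probes=cohort.beta.probe_ids[:20])
        out = mm.select_candidates(sub, cohort.samples.groups, q_threshold=1.0)
        assert out == list(sub.probe_ids)

    def test_null_matrix_selects_nothing(self):
        cohort = mm.simulate_cohort(n_probes=100, n_dml=0, delta=0.0, seed=23)
        out = mm.select_candidates(cohort.beta, cohort.samples.groups)
        assert out == []


class TestFitLogistic:
    def test_perfect_separation_flagged_with_unit_auc(self):
        X = pd.DataFrame({"cpg": [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]})
        y = [1, 1, 1, 0, 0, 0]
        m = mm.fit_logistic(X, y)
        assert m.auc == pytest.approx(1.0)
        assert m.separation_flag

    def test_constant_feature_rejected(self):
        X = pd.DataFrame({"cpg": [0.5] * 8})
        with pytest.raises(ValueError, match="constant"):
            mm.fit_logistic(X, [0, 1, 0, 1, 0, 1, 0, 1])

    def test_independent_feature_has_half_auc(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"cpg": rng.random(2000)})
        y = rng.integers(0, 2, 2000)
        m = mm.fit_logistic(X, y)
        assert m.auc == pytest.approx(0.5, abs=0.05)

    def test_parameter_recovery_at_n500(self):
        """Data generated from (b0=6.1, b1=−10) refits within 15%."""
        X, y = _logistic_data(6.1, -10.0, 500, seed=10)
        m = mm.fit_logistic(X, y)
        assert abs(m.intercept - 6.1) / 6.1 <= 0.15
        assert abs(m.coefficients[0] + 10.0) / 10.0 <= 0.15

    def test_auc_invariant_to_monotone_feature_transform(self):
        X, y = _logistic_data(3.0, -6.0, 200, seed=11)
        m1 = mm.fit_logistic(X, y)
        m2 = mm.fit_logistic(np.exp(X), y)
        assert m1.auc == pytest.approx(m2.auc, abs=1e-12)

    def test_group_labels_accepted_as_outcome(self):
        X, y = _logistic_data(3.0, -6.0, 50, seed=12)
        labels = pd.Series(np.where(y == 1, "IR", "IS"), index=X.index)
        m = mm.fit_logistic(X, labels)
        assert m.n_used == 50


class TestBetaCutoff:
    def _model(self, b0, b1):
        return LogisticModel(
            name="m", feature_names=["cpg"], intercept=b0,
            coefficients=np.array([b1]), auc=1.0, n_used=0,
            sample_index=pd.Index([]),
        )

    def test_cutoff_algebra(self):
        """b0=6.1, b1=−10 ⇒ cutoff 0.61 with a 'β < 0.61 ⇒ IR' rule."""
        m = self._model(6.1, -10.0)
        X = pd.DataFrame({"cpg": [0.5, 0.7]})
        res = mm.beta_cutoff(m, X, [1, 0])
        assert res.cutoff == pytest.approx(0.61)
        assert res.rule.startswith("beta <")
        assert res.accuracy_ir == 1.0 and res.accuracy_is == 1.0

    def test_cutoff_sits_at_probability_half(self):
        X, y = _logistic_data(6.1, -10.0, 300, seed=13)
        m = mm.fit_logistic(X, y)
        res = mm.beta_cutoff(m, X, y)
        prob = m.predict_proba(pd.DataFrame({"cpg": [res.cutoff]}))[0]
        assert prob == pytest.approx(0.5, abs=1e-8)

    def test_per_class_accuracy_fractions(self):
        """9 of 14 IR below the cutoff gives 64.3% IR accuracy (and the IS
        fraction is counted on the other side)."""
        m = self._model(6.1, -10.0)  # cutoff 0.61, IR side is below
        ir_x = [0.5] * 9 + [0.7] * 5     # 9 of 14 on the IR side
        is_x = [0.8] * 20 + [0.5] * 3    # 20 of 23 on the IS side
        X = pd.DataFrame({"cpg": ir_x + is_x})
        y = [1] * 14 + [0] * 23
        res = mm.beta_cutoff(m, X, y)
        assert res.accuracy_ir == pytest.approx(9 / 14)
        assert round(100 * res.accuracy_ir, 1) == 64.3
        assert res.accuracy_is == pytest.approx(20 / 23)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="zero coefficient"):
            mm.beta_cutoff(self._model(1.0, 0.0), pd.DataFrame({"cpg": [0.5]}), [1])

    def test_multifeature_model_rejected(self):
        m = LogisticModel(
            name="m", feature_names=["a", "b"], intercept=0.0,
            coefficients=np.array([1.0, 1.0]), auc=0.5, n_used=0,
            sample_index=pd.Index([]),
        )
        with pytest.raises(ValueError, match="single-feature"):
            mm.beta_cutoff(m, pd.DataFrame({"a": [1], "b": [2]}), [1])


class TestStepwise:
    def _features(self, seed, n=120):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {f"noise{i}": rng.random(n) for i in range(5)},
            index=[f"s{i}" for i in range(n)],
        )
        signal = rng.uniform(0.2, 1.0, n)
        p = 1 / (1 + np.exp(-(4.0 - 8.0 * signal)))
        y = (rng.random(n) < p).astype(int)
        X.insert(2, "informative", signal)
        return X, pd.Series(y, index=X.index)

    def test_informative_feature_enters_first(self):
        X, y = self._features(seed=20)
        m = mm.stepwise_select(X, y)
        assert m.extras["stepwise_path"][1][0] == "informative"

    def test_collinear_copy_enters_once(self):
        X, y = self._features(seed=21)
        X["informative_copy"] = X["informative"]
        m = mm.stepwise_select(X, y)
        assert sum(f.startswith("informative") for f in m.feature_names) == 1

    def test_all_noise_returns_intercept_only(self):
        rng = np.random.default_rng(22)
        X = pd.DataFrame({f"n{i}": rng.random(60) for i in range(4)})
        y = rng.integers(0, 2, 60)
        m = mm.stepwise_select(X, y)
        assert m.feature_names == []


class TestCompareModels:
    def _model(self, name, auc, nfeat, index):
        return LogisticModel(
            name=name, feature_names=[f"f{i}" for i in range(nfeat)],
            intercept=0.0, coefficients=np.zeros(nfeat), auc=auc,
            n_used=len(index), sample_index=index,
        )

    def test_ties_broken_by_fewer_features(self):
        idx = pd.Index(["a", "b", "c"])
        table = mm.compare_models(
            [self._model("big", 0.9, 3, idx), self._model("small", 0.9, 1, idx)]
        )
        assert table.iloc[0]["model"] == "small"

    def test_different_sample_sets_rejected(self):
        with pytest.raises(ValueError, match="different sample set"):
            mm.compare_models(
                [self._model("m1", 0.9, 1, pd.Index(["a", "b"])),
                 self._model("m2", 0.8, 1, pd.Index(["a", "c"]))]
            )

    def test_methylation_beats_clinical_when_only_methylation_informative(self, cohort):
        """On a cohort where group signal lives in the planted CpGs, a
        single-CpG model outranks a pure-noise 'clinical' model."""
        groups = cohort.samples.groups
        best_probe = (
            cohort.truth.loc[cohort.truth["is_planted_dml"], "true_delta"]
            .abs().idxmax()
        )
        cpg = mm.single_cpg_models(cohort.beta, groups, [best_probe])[0]
        rng = np.random.default_rng(30)
        clinical = pd.DataFrame(
            {"sham_marker": rng.random(len(groups))}, index=groups.index
        )
        clin = mm.fit_logistic(clinical, groups, name="sham_marker")
        ranked = mm.compare_models([cpg, clin])
        assert ranked.iloc[0]["model"] == best_probe
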