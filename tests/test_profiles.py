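import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from morphpair import profiles, synthio
from morphpair.profiles import (
    CONTROL,
    GENERALLY_POOR_READER,
    POOR_COMPREHENDER,
    POOR_DECODER,
    UNCLASSIFIABLE,
)

from conftest import small_config
from oracles import cronbach_alpha_longhand


def subject(**kw):
    base = dict(word_attack=100.0, word_id=100.0, passage_comp=100.0,
                verbal_comp=100.0, ran=100.0, age=10.0)
    base.update(kw)
    return base


class TestExpertRules:
    def test_poor_decoder_example(self):
        s = subject(verbal_comp=102, word_attack=82, word_id=84,
                    passage_comp=85, ran=84)
        assert profiles.classify_expert_rules(s) == POOR_DECODER

    def test_control_example(self):
        assert profiles.classify_expert_rules(subject()) == CONTROL

    def test_poor_comprehender_example(self):
        s = subject(verbal_comp=105, word_attack=98, word_id=84,
                    passage_comp=83, ran=95, age=10)
        assert profiles.classify_expert_rules(s) == POOR_COMPREHENDER

    def test_generally_poor_reader(self):
        s = subject(verbal_comp=82, word_attack=80, word_id=83,
                    passage_comp=81, ran=85)
        assert profiles.classify_expert_rules(s) == GENERALLY_POOR_READER

    def test_young_comprehender_is_unclassifiable(self):
        s = subject(verbal_comp=105, word_attack=98, word_id=84,
                    passage_comp=83, ran=95, age=7)
        assert profiles.classify_expert_rules(s) == UNCLASSIFIABLE

    def test_missing_score_errors(self):
        s = subject()
        del s["ran"]
        with pytest.raises(ValueError, match="ran"):
            profiles.classify_expert_rules(s)
        with pytest.raises(ValueError):
            profiles.classify_expert_rules(subject(word_id=np.nan))

    def test_total_function_on_random_inputs(self, rng):
        for _ in range(200):
            s = subject(**{k: float(rng.uniform(55, 145)) for k in
                           ("word_attack", "word_id", "passage_comp",
                            "verbal_comp", "ran")},
                        age=float(rng.uniform(6, 14)))
            assert profiles.classify_expert_rules(s) in profiles.PROFILE_LABELS

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            profiles.RuleSet(verbal_min=0.0)


class TestEnsembleLoocv:
    def test_identical_features_majority_rate(self):
        n_a, n_b = 14, 6
        frame = pd.DataFrame([subject()] * (n_a + n_b))
        labels = [CONTROL] * n_a + [POOR_DECODER] * n_b
        pred, acc, prob = profiles.classify_ensemble_loocv(
            frame, labels, n_trees=150, seed=0)
        majority = n_a / (n_a + n_b)
        assert abs(acc - majority) < 0.15
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_swapped_label_symmetry(self):
        # identical features, balanced opposing labels -> votes near 0.5
        frame = pd.DataFrame([subject()] * 20)
        labels = [CONTROL, POOR_DECODER] * 10
        _, _, prob = profiles.classify_ensemble_loocv(
            frame, labels, n_trees=300, seed=1)
        mean_control_vote = prob[CONTROL].mean()
        assert abs(mean_control_vote - 0.5) < 0.1

    def test_separated_cohort_high_accuracy(self):
        cfg = small_config(n_per_site=(4,) * 8, seed=21)
        cohort = synthio.generate_cohort(cfg)
        pred, acc, prob = profiles.classify_ensemble_loocv(
            cohort, cohort["true_profile"], n_trees=200, seed=2)
        assert acc >= 0.9
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-9)

    def test_single_class_rejected(self):
        frame = pd.DataFrame([subject()] * 5)
        with pytest.raises(ValueError):
            profiles.classify_ensemble_loocv(frame, [CONTROL] * 5)

    def test_singleton_class_warns(self):
        frame = pd.DataFrame([subject()] * 5)
        labels = [CONTROL] * 4 + [POOR_DECODER]
        with pytest.warns(UserWarning, match="single member"):
            profiles.classify_ensemble_loocv(frame, labels, n_trees=20, seed=0)

    def test_seeded_determinism(self):
        cfg = small_config(n_per_site=(3,) * 8, seed=8)
        cohort = synthio.generate_cohort(cfg)
        out1 = profiles.classify_ensemble_loocv(
            cohort, cohort["true_profile"], n_trees=50, seed=11)
        out2 = profiles.classify_ensemble_loocv(
            cohort, cohort["true_profile"], n_trees=50, seed=11)
        pd.testing.assert_frame_equal(out1[2], out2[2])
        assert out1[1] == out2[1]


class TestVariableImportance:
    def test_noise_feature_near_zero(self, rng):
        cfg = small_config(n_per_site=(4,) * 8, seed=13)
        cohort = synthio.generate_cohort(cfg).copy()
        cohort["noise_feat"] = rng.normal(size=len(cohort))
        imp = profiles.variable_importance(
            cohort, cohort["true_profile"], n_trees=150,
            features=profiles.FEATURE_COLUMNS + ("noise_feat",), seed=3)
        assert abs(imp["noise_feat"]) <= 2.0

    def test_single_informative_feature_ranks_first(self, rng):
        n = 60
        frame = pd.DataFrame({
            "word_attack": np.r_[rng.normal(80, 3, n // 2),
                                 rng.normal(115, 3, n // 2)],
            "word_id": rng.normal(100, 10, n),
            "passage_comp": rng.normal(100, 10, n),
            "verbal_comp": rng.normal(100, 10, n),
            "ran": rng.normal(100, 10, n),
            "age": rng.uniform(7, 13, n),
        })
        labels = [POOR_DECODER] * (n // 2) + [CONTROL] * (n // 2)
        imp = profiles.variable_importance(frame, labels, n_trees=150, seed=4)
        assert max(imp, key=imp.get) == "word_attack"


class TestCronbachAlpha:
    def test_identical_columns(self, rng):
        col = rng.normal(size=30)
        rep = profiles.cronbach_alpha(np.column_stack([col, col]))
        assert rep.cronbach_alpha == pytest.approx(1.0)

    def test_hand_computed_example(self):
        ratings = np.array([[1, 1], [2, 2], [3, 4]], dtype=float)
        rep = profiles.cronbach_alpha(ratings)
        assert rep.cronbach_alpha == pytest.approx(
            cronbach_alpha_longhand(ratings), abs=1e-12)

    def test_independent_columns_near_zero(self, rng):
        R = rng.normal(size=(1000, 2))
        rep = profiles.cronbach_alpha(R)
        assert abs(rep.cronbach_alpha) < 0.1

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            profiles.cronbach_alpha(np.ones((5, 2)))

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_alpha_never_exceeds_one(self, seed):
        r = np.random.default_rng(seed)
        R = r.normal(size=(r.integers(3, 12), r.integers(2, 5)))
        try:
            rep = profiles.cronbach_alpha(R)
        except ValueError:
            return
        assert rep.cronbach_alpha <= 1.0 + 1e-12

    def test_shifted_columns_equal_one(self, rng):
        col = rng.normal(size=25)
        rep = profiles.cronbach_alpha(np.column_stack([col, col + 3.0, col - 1.0]))
        assert rep.cronbach_alpha == pytest.approx(1.0)


class TestClassicalMds:
    def test_collinear_points(self):
        prob = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        dims = profiles.classical_mds(prob, k=2)
        d1 = dims.coords["dim1"].to_numpy()
        np.testing.assert_allclose(sorted(np.abs(d1)), [0, 1, 1], atol=1e-9)
        np.testing.assert_allclose(dims.coords["dim2"], 0.0, atol=1e-7)

    def test_distance_recovery_2d(self, rng):
        pts = rng.normal(size=(10, 2))
        prob = pd.DataFrame(pts, columns=["a", "b"])
        dims = profiles.classical_mds(prob, k=2)
        orig = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        rec = dims.coords.to_numpy()
        recd = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
        np.testing.assert_allclose(recd, orig, atol=1e-8)

    def test_k_too_large_errors(self):
        prob = pd.DataFrame({"a": [0.0, 1.0]})
        with pytest.raises(ValueError):
            profiles.classical_mds(prob, k=2)

    def test_gof_definition(self, rng):
        prob = pd.DataFrame(rng.dirichlet(np.ones(4), size=15))
        dims = profiles.classical_mds(prob, k=2)
        lam = dims.eigenvalues
        expected = lam[:2].sum() / np.abs(lam).sum()
        assert dims.goodness_of_fit == pytest.approx(expected)
        assert 0 <= dims.goodness_of_fit <= 1

    def test_sign_convention_deterministic(self, rng):
        prob = pd.DataFrame(rng.dirichlet(np.ones(4), size=12))
        a = profiles.classical_mds(prob, k=2).coords
        b = profiles.classical_mds(prob.copy(), k=2).coords
        pd.testing.assert_frame_equal(a, b)


class TestDimensionAnova:
    def _dims(self, values, labels):
        coords = pd.DataFrame({"dim1": values})
        lam = np.array([1.0, 0.5])
        ds = profiles.DimensionScores(coords=coords, eigenvalues=lam,
                                      goodness_of_fit=1.0)
        return ds, labels

    def test_two_groups_f_equals_t_squared(self, rng):
        x = rng.normal(size=24)
        labels = np.array(["a"] * 12 + ["b"] * 12)
        ds, labels = self._dims(x, labels)
        res = profiles.dimension_anova(ds, labels)["dim1"]
        t = sps.ttest_ind(x[:12], x[12:]).statistic
        assert res["F"] == pytest.approx(t ** 2, rel=1e-10)

    def test_separated_groups_significant(self, rng):
        x = np.concatenate([rng.normal(m, 0.1, 20) for m in (-1, 0, 1)])
        labels = np.repeat(["a", "b", "c"], 20)
        res = profiles.dimension_anova(*self._dims(x, labels))["dim1"]
        assert res["p"] < 0.001
        assert all(p < 0.01 for p in res["tukey"].values())

    def test_null_groups_not_tiny_p(self, rng):
        x = rng.normal(size=300)
        labels = np.repeat(["a", "b", "c"], 100)
        res = profiles.dimension_anova(*self._dims(x, labels))["dim1"]
        assert res["p"] > 1e-4

    def test_small_group_errors(self):
        ds, labels = self._dims(np.arange(4.0), np.array(["a", "a", "a", "b"]))
        with pytest.raises(ValueError):
            profiles.dimension_anova(ds, labels)
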