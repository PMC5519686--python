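import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from morphpair import matching, synthio

from conftest import small_config
from oracles import yates_chi2_longhand


def toy_subjects(brain_sizes, cases, site=1, **extra):
    n = len(brain_sizes)
    frame = pd.DataFrame({
        "subject_id": [f"s{i:02d}" for i in range(n)],
        "site": [site] * n if np.isscalar(site) else site,
        "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2),
        "age": np.linspace(8, 12, n),
        "gm_volume": np.asarray(brain_sizes) * 0.6,
        "wm_volume": np.asarray(brain_sizes) * 0.4,
        "brain_size": np.asarray(brain_sizes, dtype=float),
        "is_case": cases,
    })
    for k, v in extra.items():
        frame[k] = v
    return frame


class TestStratify:
    def test_median_split_example(self):
        subjects = toy_subjects([900, 1000, 1100, 1200],
                                [True, False, True, False])
        strata = matching.stratify(subjects)
        assert len(strata) == 2
        by_bin = {s.size_bin: set(s.member_ids) for s in strata}
        assert by_bin["smaller"] == {"s00", "s01"}
        assert by_bin["larger"] == {"s02", "s03"}

    def test_control_only_site_dropped(self):
        subjects = pd.concat([
            toy_subjects([900, 1000, 1100, 1200], [True, False, True, False], site=1),
            toy_subjects([950, 1050], [False, False], site=2).assign(
                subject_id=["t0", "t1"]),
        ], ignore_index=True)
        strata = matching.stratify(subjects)
        assert {s.site for s in strata} == {1}

    def test_every_stratum_mixed(self, default_cohort):
        strata = matching.stratify(default_cohort)
        frame = default_cohort.set_index("subject_id")
        for st in strata:
            flags = frame.loc[st.member_ids, "is_case"]
            assert flags.any() and (~flags).any()
            assert frame.loc[st.member_ids, "site"].nunique() == 1

    def test_cem_weight_formula(self):
        subjects = toy_subjects(
            [900, 910, 920, 1100, 1110, 1120],
            [True, False, False, True, True, False])
        strata = matching.stratify(subjects)
        total_cases, total_controls = 3, 3
        for st in strata:
            flags = subjects.set_index("subject_id").loc[st.member_ids, "is_case"]
            expected = ((~flags).sum() / flags.sum()) * (total_cases / total_controls)
            assert st.cem_weight == pytest.approx(expected)

    def test_single_subject_errors(self):
        with pytest.raises(ValueError):
            matching.stratify(toy_subjects([1000], [True]))


class TestPropensity:
    def test_null_model_scores_equal_prevalence(self, rng):
        n = 400
        subjects = toy_subjects(rng.normal(1100, 60, n),
                                [True] * 100 + [False] * 300)
        model = matching.fit_propensity(subjects)
        np.testing.assert_allclose(model.scores, 0.25, atol=0.12)
        assert model.scores.between(0, 1, inclusive="neither").all()

    def test_deterministic_separation_flagged(self):
        bs = np.linspace(1000, 1200, 20)
        subjects = toy_subjects(bs, list(bs < 1100))
        model = matching.fit_propensity(subjects)
        assert model.separation_flag

    def test_coefficient_recovery(self, rng):
        # known-coefficient simulation: beta_size = -0.01 per cm^3, n = 2000
        n = 2000
        bs = rng.normal(1150, 80, n)
        beta0, beta_size = 11.5, -0.01
        p = 1 / (1 + np.exp(-(beta0 + beta_size * bs)))
        cases = rng.random(n) < p
        subjects = toy_subjects(bs, list(cases))
        model = matching.fit_propensity(subjects)
        X = sm.add_constant(bs)
        se = sm.Logit(cases.astype(float), X).fit(disp=0).bse[1]
        assert abs(model.coefficients["brain_size"] - beta_size) < 2 * se

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            matching.fit_propensity(toy_subjects([1000, 1100], [True, True]))


class TestPairNearest:
    def _setup(self, subjects):
        strata = matching.stratify(subjects)
        model = matching.fit_propensity(subjects)
        return strata, model

    def test_one_case_one_control(self):
        subjects = toy_subjects([1000, 1010, 1300, 1310],
                                [True, False, True, False])
        strata, model = self._setup(subjects)
        pairs = matching.pair_nearest(strata, model, subjects)
        assert pairs.n_pairs == 2
        assert set(zip(pairs.pairs.case_id, pairs.pairs.control_id)) == {
            ("s00", "s01"), ("s02", "s03")}

    def test_two_cases_one_control(self):
        # smaller bin holds 2 cases + 1 control; larger bin is control-only
        subjects = toy_subjects([1000, 1001, 1002, 1300, 1301, 1302],
                                [True, True, False, False, False, False])
        strata, model = self._setup(subjects)
        pairs = matching.pair_nearest(strata, model, subjects)
        assert pairs.n_pairs == 1
        assert pairs.pairs.loc[0, "control_id"] == "s02"
        # leftover case + the controls of the dropped one-class stratum
        assert len(pairs.unmatched) == 4

    def test_uniqueness_invariant(self, matched_setup):
        pairs = matched_setup["pairs"].pairs
        ids = list(pairs.case_id) + list(pairs.control_id)
        assert len(ids) == len(set(ids))

    def test_pairs_share_site(self, matched_setup):
        frame = matched_setup["cohort"].set_index("subject_id")
        pairs = matched_setup["pairs"].pairs
        case_sites = frame.loc[pairs.case_id, "site"].to_numpy()
        control_sites = frame.loc[pairs.control_id, "site"].to_numpy()
        np.testing.assert_array_equal(case_sites, control_sites)

    def test_greedy_vs_bruteforce_optimal(self, rng):
        # brute-force assignment enumeration oracle on one stratum
        for trial in range(5):
            bs = np.concatenate([rng.uniform(1000, 1100, 5),
                                 rng.uniform(1000, 1100, 5)])
            subjects = toy_subjects(bs, [True] * 5 + [False] * 5)
            strata, model = self._setup(subjects)
            greedy = matching.pair_nearest(strata, model, subjects,
                                           method="greedy")
            optimal = matching.pair_nearest(strata, model, subjects,
                                            method="optimal")
            # oracle: exhaustive search over all control permutations per stratum
            best = 0.0
            for st in strata:
                frame = subjects.set_index("subject_id")
                members = frame.loc[st.member_ids]
                cs = list(members[members.is_case].index)
                ks = list(members[~members.is_case].index)
                scores = model.scores
                sd_p = scores.loc[[m for s in strata for m in s.member_ids]].std(ddof=1) or 1.0
                sd_b = frame.loc[[m for s in strata for m in s.member_ids],
                                 "brain_size"].std(ddof=1) or 1.0

                def dist(c, k):
                    return st.cem_weight * (
                        abs(scores[c] - scores[k]) / sd_p
                        + abs(frame.at[c, "brain_size"]
                              - frame.at[k, "brain_size"]) / sd_b)
                m = min(len(cs), len(ks))
                # enumerate case subsets/orders and control orders so the
                # oracle also optimizes which cases get matched
                best += min(
                    sum(dist(c, k) for c, k in zip(cperm, kperm))
                    for cperm in itertools.permutations(cs, m)
                    for kperm in itertools.permutations(ks, m))
            assert optimal.pairs.distance.sum() == pytest.approx(best, rel=1e-9)
            assert greedy.pairs.distance.sum() >= best - 1e-12

    def test_deterministic(self, matched_setup):
        again = matching.pair_nearest(matched_setup["strata"],
                                      matched_setup["model"],
                                      matched_setup["cohort"])
        pd.testing.assert_frame_equal(again.pairs, matched_setup["pairs"].pairs)


class TestRandomPairing:
    def test_single_pair(self):
        subjects = toy_subjects([1000, 1100], [True, False])
        pairs = matching.random_pairing(subjects, seed=0)
        assert pairs.n_pairs == 1

    def test_seeded_determinism(self, default_cohort):
        a = matching.random_pairing(default_cohort, seed=3)
        b = matching.random_pairing(default_cohort, seed=3)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_uniformity(self):
        subjects = toy_subjects([1000, 1010, 1020, 1100, 1110, 1120],
                                [True, True, True, False, False, False])
        target_case = "s00"
        counts = {"s03": 0, "s04": 0, "s05": 0}
        n_seeds = 1000
        for seed in range(n_seeds):
            pairs = matching.random_pairing(subjects, seed=seed).pairs
            control = pairs.loc[pairs.case_id == target_case, "control_id"].iloc[0]
            counts[control] += 1
        for c in counts.values():
            assert abs(c / n_seeds - 1 / 3) < 0.05

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            matching.random_pairing(toy_subjects([1000, 1100], [True, True]))


class TestBalance:
    def test_printed_sex_table(self):
        stat, df, p = matching.yates_chi_square([[24, 43], [28, 39]])
        assert round(stat, 2) == 0.28
        assert df == 1
        assert p == pytest.approx(0.59, abs=0.005)

    def test_yates_matches_longhand_formula(self, rng):
        for _ in range(300):
            table = rng.integers(1, 60, size=(2, 2))
            stat, _, _ = matching.yates_chi_square(table)
            assert stat == pytest.approx(yates_chi2_longhand(table), rel=1e-12)

    def test_identical_covariates_p_one(self):
        subjects = toy_subjects([1000, 1000, 1200, 1200],
                                [True, False, True, False])
        subjects["age"] = [9, 9, 11, 11]
        strata = matching.stratify(subjects)
        model = matching.fit_propensity(subjects)
        pairs = matching.pair_nearest(strata, model, subjects)
        report = matching.balance_diagnostics(pairs, subjects)
        for var in ("age", "gm_volume", "wm_volume", "brain_size"):
            assert report.entries[var]["statistic"] == 0.0
            assert report.entries[var]["p"] == 1.0

    def test_full_report_structure(self, matched_setup):
        cohort = matched_setup["cohort"]
        labels = cohort.set_index("subject_id")["true_profile"]
        case_labels = labels.loc[matched_setup["pairs"].pairs.case_id]
        report = matching.balance_diagnostics(
            matched_setup["pairs"], cohort, matched_setup["model"], case_labels)
        frame = report.to_frame()
        assert {"age", "gm_volume", "wm_volume", "brain_size", "sex",
                "propensity"} <= set(frame.index)
        assert ((frame["p"] >= 0) & (frame["p"] <= 1)).all()

    def test_statistics_reproducible_from_pair_table(self, matched_setup):
        cohort = matched_setup["cohort"].set_index("subject_id")
        pairs = matched_setup["pairs"].pairs
        report = matching.balance_diagnostics(matched_setup["pairs"],
                                              matched_setup["cohort"])
        d = (cohort.loc[pairs.case_id, "age"].to_numpy()
             - cohort.loc[pairs.control_id, "age"].to_numpy())
        t_expected = sps.ttest_1samp(d, 0.0).statistic
        assert report.entries["age"]["statistic"] == pytest.approx(t_expected)

    def test_matching_reduces_brain_size_imbalance(self):
        # directional property: matched pairs shrink the standardized
        # brain-size gap relative to random cross-site pairing
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = small_config(seed=seed)
            cohort = synthio.generate_cohort(cfg)
            frame = cohort.set_index("subject_id")
            strata = matching.stratify(cohort)
            model = matching.fit_propensity(cohort)
            matched = matching.pair_nearest(strata, model, cohort).pairs
            rand = matching.random_pairing(cohort, seed=seed).pairs

            def gap(pairs):
                d = (frame.loc[pairs.case_id, "brain_size"].to_numpy()
                     - frame.loc[pairs.control_id, "brain_size"].to_numpy())
                return np.abs(d).mean()
            wins += gap(matched) < gap(rand)
        assert wins >= 8
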