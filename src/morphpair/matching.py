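"""Case-control pairing: coarsened stratification, propensity scores,
within-stratum nearest-neighbor pairing, balance diagnostics, random pairing.

Strata coarsen brain size at the site-wise median (smaller/larger) within each
research site; a logistic model of case status on site and total brain size
supplies propensity scores; unique pairs are then drawn greedily (or by
optimal assignment) within strata using a standardized propensity +
brain-size distance scaled by the stratum's coarsened-matching weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression

__all__ = [
    "Stratum",
    "PropensityModel",
    "MatchedPairSet",
    "BalanceReport",
    "stratify",
    "fit_propensity",
    "pair_nearest",
    "random_pairing",
    "balance_diagnostics",
    "yates_chi_square",
]

SMALLER, LARGER = "smaller", "larger"


@dataclass
class Stratum:
    site: int
    size_bin: str  # smaller | larger
    member_ids: list
    cem_weight: float  # weight applied to the stratum's controls; cases weigh 1

    @property
    def key(self):
        return (self.site, self.size_bin)


@dataclass
class PropensityModel:
    coefficients: dict
    scores: pd.Series  # indexed by subject_id, values in (0, 1)
    converged: bool
    separation_flag: bool


@dataclass
class MatchedPairSet:
    """Unique case-control pairs; no subject appears in more than one pair."""

    pairs: pd.DataFrame  # columns case_id, control_id, stratum, distance
    unmatched: list = field(default_factory=list)

    def __post_init__(self):
        ids = list(self.pairs["case_id"]) + list(self.pairs["control_id"])
        if len(ids) != len(set(ids)):
            raise ValueError("a subject occurs in more than one pair")

    @property
    def n_pairs(self):
        return len(self.pairs)

    def to_csv(self, path):
        self.pairs.to_csv(path, index=False)


def _subject_frame(subjects: pd.DataFrame) -> pd.DataFrame:
    frame = subjects.set_index("subject_id", drop=False)
    frame["is_case"] = frame["is_case"].astype(bool)
    return frame


def stratify(subjects: pd.DataFrame, quantile: float = 0.5) -> list:
    """Split each site at its ``quantile`` brain size; drop one-class strata.

    The coarsened-matching weight of a stratum's controls is
    (stratum controls / stratum cases) * (total cases / total controls),
    computed over the retained strata; cases carry weight 1.
    """
    frame = _subject_frame(subjects)
    if len(frame) < 2:
        raise ValueError("need at least 2 subjects to stratify")
    raw = []
    for site, grp in frame.groupby("site"):
        cut = float(np.quantile(grp["brain_size"], quantile))
        for name, sel in ((SMALLER, grp["brain_size"] <= cut),
                          (LARGER, grp["brain_size"] > cut)):
            sub = grp.loc[sel]
            if sub.empty:
                continue
            if sub["is_case"].any() and (~sub["is_case"]).any():
                raw.append((int(site), name, sub))
    if not raw:
        raise ValueError("no stratum contains both a case and a control")
    total_cases = sum(int(s["is_case"].sum()) for _, _, s in raw)
    total_controls = sum(int((~s["is_case"]).sum()) for _, _, s in raw)
    strata = []
    for site, name, sub in raw:
        n_case = int(sub["is_case"].sum())
        n_ctrl = int((~sub["is_case"]).sum())
        w = (n_ctrl / n_case) * (total_cases / total_controls)
        strata.append(Stratum(site=site, size_bin=name,
                              member_ids=list(sub["subject_id"]), cem_weight=w))
    return strata


def fit_propensity(subjects: pd.DataFrame) -> PropensityModel:
    """Logistic regression of case status on site indicators + brain size.

    Maximum-likelihood fit; on (quasi-)separation or non-convergence the model
    is re-fit with an L2 penalty and flagged.
    """
    frame = _subject_frame(subjects)
    y = frame["is_case"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both cases and controls are required")
    site_dummies = pd.get_dummies(frame["site"], prefix="site", drop_first=True,
                                  dtype=float)
    X = pd.concat([site_dummies, frame[["brain_size"]]], axis=1)
    Xd = sm.add_constant(X, has_constant="add")

    separation = False
    converged = False
    params = None
    fitted = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params = res.params
            fitted = res.predict()
        except Exception:
            separation = True
    if fitted is not None and (
            not converged or fitted.min() < 1e-10 or fitted.max() > 1 - 1e-10
            or np.abs(params).max() > 1e3):
        separation = True
    if separation:
        lr = LogisticRegression(C=1.0, max_iter=1000)  # L2-penalized fallback
        lr.fit(X.to_numpy(dtype=float), y)
        params = np.concatenate([lr.intercept_, lr.coef_[0]])
        fitted = lr.predict_proba(X.to_numpy(dtype=float))[:, 1]
        converged = True
    coef = dict(zip(["const"] + list(X.columns), np.asarray(params, dtype=float)))
    scores = pd.Series(np.clip(fitted, 1e-12, 1 - 1e-12),
                       index=frame.index, name="propensity")
    return PropensityModel(coefficients=coef, scores=scores,
                           converged=converged, separation_flag=separation)


def _pair_distance_terms(frame, model, strata):
    in_strata = sorted({sid for s in strata for sid in s.member_ids})
    prop = model.scores.loc[in_strata]
    bs = frame.loc[in_strata, "brain_size"]
    sd_p = float(prop.std(ddof=1)) or 1.0
    sd_b = float(bs.std(ddof=1)) or 1.0
    return sd_p, sd_b


def pair_nearest(
    strata,
    model: PropensityModel,
    subjects: pd.DataFrame,
    *,
    propensity_weight: float = 1.0,
    size_weight: float = 1.0,
    use_cem_weight: bool = True,
    method: str = "greedy",
) -> MatchedPairSet:
    """Unique within-stratum pairs minimizing a standardized distance.

    distance = cem_weight * (w_p |dPropensity| / sd_p + w_s |dBrainSize| / sd_b).
    ``method='greedy'`` processes cases in deterministic order (descending
    |score - stratum mean score|, ties by id), each taking the closest unused
    control.  ``method='optimal'`` solves the within-stratum assignment
    problem exactly.  Unmatched subjects are reported, not dropped silently.
    """
    if method not in ("greedy", "optimal"):
        raise ValueError("method must be 'greedy' or 'optimal'")
    frame = _subject_frame(subjects)
    sd_p, sd_b = _pair_distance_terms(frame, model, strata)
    rows, unmatched = [], []
    matched_ids = set()
    for st in strata:
        members = frame.loc[st.member_ids]
        cases = members.loc[members["is_case"]]
        controls = members.loc[~members["is_case"]]
        cw = st.cem_weight if use_cem_weight else 1.0
        p_all = model.scores.loc[st.member_ids]
        center = float(p_all.mean())

        def dist(cid, kid):
            dp = abs(model.scores[cid] - model.scores[kid]) / sd_p
            db = abs(frame.at[cid, "brain_size"] - frame.at[kid, "brain_size"]) / sd_b
            return cw * (propensity_weight * dp + size_weight * db)

        case_ids = sorted(
            cases["subject_id"],
            key=lambda cid: (-abs(model.scores[cid] - center), cid))
        control_ids = sorted(controls["subject_id"])
        if method == "optimal" and case_ids and control_ids:
            D = np.array([[dist(c, k) for k in control_ids] for c in case_ids])
            ri, ci = linear_sum_assignment(D)
            for r, c in zip(ri, ci):
                rows.append({"case_id": case_ids[r], "control_id": control_ids[c],
                             "site": st.site, "stratum": f"{st.site}:{st.size_bin}",
                             "distance": float(D[r, c])})
                matched_ids.update((case_ids[r], control_ids[c]))
        else:
            free = list(control_ids)
            for cid in case_ids:
                if not free:
                    break
                best = min(free, key=lambda k: (dist(cid, k), k))
                rows.append({"case_id": cid, "control_id": best,
                             "site": st.site, "stratum": f"{st.site}:{st.size_bin}",
                             "distance": float(dist(cid, best))})
                matched_ids.update((cid, best))
                free.remove(best)
    stratum_ids = {sid for s in strata for sid in s.member_ids}
    unmatched = sorted(set(frame["subject_id"]) - matched_ids)
    pairs = pd.DataFrame(rows, columns=["case_id", "control_id", "site",
                                        "stratum", "distance"])
    return MatchedPairSet(pairs=pairs, unmatched=unmatched)


def random_pairing(subjects: pd.DataFrame, seed=None) -> MatchedPairSet:
    """Uniform random case-control bijection ignoring site and brain size.

    If group sizes differ, the larger group is truncated at random.
    """
    frame = _subject_frame(subjects)
    cases = list(frame.loc[frame["is_case"], "subject_id"])
    controls = list(frame.loc[~frame["is_case"], "subject_id"])
    if not cases or not controls:
        raise ValueError("both cases and controls are required")
    rng = np.random.default_rng(seed)
    n = min(len(cases), len(controls))
    cases = list(rng.permutation(cases))[:n]
    controls = list(rng.permutation(controls))[:n]
    pairs = pd.DataFrame({
        "case_id": cases, "control_id": controls,
        "site": np.nan, "stratum": "random", "distance": np.nan,
    })
    matched = set(cases) | set(controls)
    unmatched = sorted(set(frame["subject_id"]) - matched)
    return MatchedPairSet(pairs=pairs, unmatched=unmatched)


def yates_chi_square(table) -> tuple:
    """Continuity-corrected chi-square for a 2x2 table: (stat, df, p)."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=True)
    return float(stat), int(df), float(p)


@dataclass
class BalanceReport:
    """Per-variable balance tests, reproducible from the pair table."""

    entries: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_dict(self.entries, orient="index")


def _paired_t(diff):
    diff = np.asarray(diff, dtype=float)
    if np.allclose(diff.var(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        return np.inf * np.sign(diff.mean()), 0.0
    t, p = stats.ttest_1samp(diff, 0.0)
    return float(t), float(p)


def balance_diagnostics(
    pairset: MatchedPairSet,
    subjects: pd.DataFrame,
    model: PropensityModel | None = None,
    profile_labels=None,
) -> BalanceReport:
    """Covariate balance of a matched-pair set.

    Paired t-tests on age / gm / wm / brain size differences, a Yates-corrected
    2x2 sex-by-group chi-square, an unpaired t on the propensity score, and
    (when profile labels are supplied) a one-way ANOVA of per-pair propensity
    differences across the reading-disability profiles.
    """
    if pairset.n_pairs < 2:
        raise ValueError("need at least 2 pairs for balance diagnostics")
    frame = _subject_frame(subjects)
    ca = pairset.pairs["case_id"].to_numpy()
    co = pairset.pairs["control_id"].to_numpy()
    entries = {}
    n = len(ca)
    for var in ("age", "gm_volume", "wm_volume", "brain_size"):
        diff = frame.loc[ca, var].to_numpy() - frame.loc[co, var].to_numpy()
        t, p = _paired_t(diff)
        entries[var] = {"test": "paired t", "statistic": t, "df": n - 1, "p": p}

    paired_ids = np.concatenate([ca, co])
    sub = frame.loc[paired_ids]
    table = np.array([
        [(sub.loc[ca, "sex"] == "F").sum(), (sub.loc[ca, "sex"] == "M").sum()],
        [(sub.loc[co, "sex"] == "F").sum(), (sub.loc[co, "sex"] == "M").sum()],
    ])
    stat, df, p = yates_chi_square(table)
    entries["sex"] = {"test": "chi-square (Yates)", "statistic": stat, "df": df, "p": p}

    if model is not None:
        pc = model.scores.loc[ca].to_numpy()
        pk = model.scores.loc[co].to_numpy()
        t, p = stats.ttest_ind(pc, pk)
        entries["propensity"] = {"test": "unpaired t", "statistic": float(t),
                                 "df": 2 * n - 2, "p": float(p)}
        if profile_labels is not None:
            lab = pd.Series(np.asarray(profile_labels), index=ca)
            pdiff = pd.Series(pc - pk, index=ca)
            groups = [pdiff[lab == g].to_numpy() for g in pd.unique(lab)]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) >= 2:
                F, p = stats.f_oneway(*groups)
                entries["propensity_by_profile"] = {
                    "test": "one-way F", "statistic": float(F),
                    "df": (len(groups) - 1, sum(len(g) for g in groups) - len(groups)),
                    "p": float(p)}
    return BalanceReport(entries=entries)
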