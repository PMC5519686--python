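"""Reading-disability profile classification and behavioral-space embedding.

Provides the deterministic expert rule set, a leave-one-out cross-validated
vote-ensemble classifier over the behavioral scores, permutation variable
importance, Cronbach's alpha reliability, classical multidimensional scaling
of class probabilities, and per-dimension ANOVA of profile effects.

Scores are stored as standard scores (population mean 100, sd 15); rule
thresholds are expressed in percentiles and compared on the percentile scale
after normal conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PROFILE_LABELS",
    "CLASS_ORDER",
    "RuleSet",
    "DimensionScores",
    "ReliabilityReport",
    "percentile_to_standard",
    "standard_to_percentile",
    "classify_expert_rules",
    "classify_cohort",
    "classify_ensemble_loocv",
    "variable_importance",
    "cronbach_alpha",
    "classical_mds",
    "dimension_anova",
]

CONTROL = "Control"
POOR_DECODER = "PoorDecoder"
POOR_COMPREHENDER = "PoorComprehender"
GENERALLY_POOR_READER = "GenerallyPoorReader"
UNCLASSIFIABLE = "Unclassifiable"

PROFILE_LABELS = (
    CONTROL,
    POOR_DECODER,
    POOR_COMPREHENDER,
    GENERALLY_POOR_READER,
    UNCLASSIFIABLE,
)

#: Column order of probability matrices (3 profiles + controls).
CLASS_ORDER = (CONTROL, POOR_DECODER, POOR_COMPREHENDER, GENERALLY_POOR_READER)

#: Behavioral features used by the ensemble classifier (five scores + age).
FEATURE_COLUMNS = ("word_attack", "word_id", "passage_comp", "verbal_comp", "ran", "age")

SCORE_COLUMNS = ("word_attack", "word_id", "passage_comp", "verbal_comp", "ran")


def percentile_to_standard(p):
    """Convert percentile(s) in (0, 100) to standard scores (mean 100, sd 15)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("percentile must lie strictly inside (0, 100)")
    out = 100.0 + 15.0 * stats.norm.ppf(p / 100.0)
    return float(out) if out.ndim == 0 else out


def standard_to_percentile(s):
    """Convert standard score(s) to percentiles in (0, 100)."""
    s = np.asarray(s, dtype=float)
    out = 100.0 * stats.norm.cdf((s - 100.0) / 15.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RuleSet:
    """Percentile thresholds of the expert classification rules.

    ``consistency_pts`` operationalizes "consistent with Word Attack": a score
    counts as consistent if it lies within that many standard-score points of
    Word Attack or falls at/below the 25th percentile.
    """

    verbal_min: float = 25.0
    word_attack_max: float = 25.0
    above_wa: float = 25.0
    pc_wid_max: float = 25.0
    ran_pd_max: float = 25.0
    ran_pc_min: float = 16.0
    poorreader_max: float = 25.0
    control_min: float = 25.0
    pc_min_age: float = 8.0
    consistency_pts: float = 10.0

    def __post_init__(self):
        for name in (
            "verbal_min", "word_attack_max", "above_wa", "pc_wid_max",
            "ran_pd_max", "ran_pc_min", "poorreader_max", "control_min",
        ):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise ValueError(f"threshold {name}={v} outside (0, 100)")


DEFAULT_RULES = RuleSet()

_REQUIRED = ("word_attack", "word_id", "passage_comp", "verbal_comp", "ran", "age")


def classify_expert_rules(subject, rules: RuleSet = DEFAULT_RULES) -> str:
    """Deterministically label one subject from its scores and age.

    ``subject`` is any mapping (dict, Series, dataclass with attributes) with
    word_attack, word_id, passage_comp, verbal_comp, ran standard scores and
    age in years.  Returns one of :data:`PROFILE_LABELS`.
    """
    get = (lambda k: subject[k]) if hasattr(subject, "__getitem__") else (
        lambda k: getattr(subject, k))
    vals = {}
    for key in _REQUIRED:
        try:
            v = get(key)
        except (KeyError, AttributeError) as exc:
            raise ValueError(f"subject missing required field {key!r}") from exc
        if v is None or not np.isfinite(v):
            raise ValueError(f"subject field {key!r} is missing or non-finite")
        vals[key] = float(v)

    wa_p = standard_to_percentile(vals["word_attack"])
    wid_p = standard_to_percentile(vals["word_id"])
    pc_p = standard_to_percentile(vals["passage_comp"])
    vc_p = standard_to_percentile(vals["verbal_comp"])
    ran_p = standard_to_percentile(vals["ran"])

    if wa_p > rules.control_min and wid_p > rules.control_min and pc_p > rules.control_min:
        return CONTROL
    if (vc_p <= rules.poorreader_max and wa_p <= rules.poorreader_max
            and wid_p <= rules.poorreader_max and pc_p <= rules.poorreader_max):
        return GENERALLY_POOR_READER

    def consistent_with_wa(score, score_p):
        return (abs(score - vals["word_attack"]) <= rules.consistency_pts
                or score_p <= rules.word_attack_max)

    if (vc_p > rules.verbal_min and wa_p < rules.word_attack_max
            and consistent_with_wa(vals["word_id"], wid_p)
            and consistent_with_wa(vals["passage_comp"], pc_p)
            and ran_p < rules.ran_pd_max):
        return POOR_DECODER
    if (vc_p > rules.verbal_min and wa_p > rules.above_wa
            and (wid_p <= rules.pc_wid_max or pc_p <= rules.pc_wid_max)
            and ran_p > rules.ran_pc_min and vals["age"] > rules.pc_min_age):
        return POOR_COMPREHENDER
    return UNCLASSIFIABLE


def classify_cohort(subjects: pd.DataFrame, rules: RuleSet = DEFAULT_RULES) -> pd.Series:
    """Apply :func:`classify_expert_rules` row-wise; indexed like ``subjects``."""
    labels = [classify_expert_rules(row, rules) for _, row in subjects.iterrows()]
    return pd.Series(labels, index=subjects.index, name="profile")


# ---------------------------------------------------------------------------
# Vote-ensemble classifier (bagged CART trees, 2 candidate features per split)
# ---------------------------------------------------------------------------

class _VoteForest:
    """Bootstrap-aggregated decision trees with per-split feature subsampling.

    Probabilities are tree vote fractions (each fully grown tree casts one
    vote), matching the classic random-forest vote semantics.  Built on
    :class:`sklearn.tree.DecisionTreeClassifier` with a thin bagging loop; the
    full bagging estimator carries avoidable per-tree overhead at this data
    size, which matters for leave-one-out runs.
    """

    def __init__(self, n_trees=500, mtry=2, rng=None):
        self.n_trees = int(n_trees)
        self.mtry = int(mtry)
        self.rng = np.random.default_rng(rng)
        self.trees_ = []
        self.classes_ = None

    def fit(self, X, y):
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        n = X.shape[0]
        seeds = self.rng.integers(0, 2**31 - 1, size=self.n_trees)
        boots = self.rng.integers(0, n, size=(self.n_trees, n))
        self.trees_ = []
        for b in range(self.n_trees):
            idx = boots[b]
            tree = DecisionTreeClassifier(
                max_features=self.mtry, random_state=int(seeds[b]))
            tree.fit(X[idx], y_enc[idx], check_input=False)
            self.trees_.append(tree)
        return self

    def vote_proba(self, X, class_order):
        """Vote fractions aligned to ``class_order`` columns."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        counts = np.zeros((X.shape[0], len(class_order)))
        col = {c: j for j, c in enumerate(class_order)}
        local_cols = np.array([col[c] for c in self.classes_])
        for tree in self.trees_:
            pred = tree.predict(X, check_input=False).astype(int)
            np.add.at(counts, (np.arange(X.shape[0]), local_cols[pred]), 1.0)
        return counts / len(self.trees_)


def classify_ensemble_loocv(
    subjects: pd.DataFrame,
    labels,
    *,
    n_trees: int = 500,
    mtry: int = 2,
    features=FEATURE_COLUMNS,
    class_order=CLASS_ORDER,
    seed=None,
):
    """Leave-one-out cross-validated ensemble classification.

    For each subject an ensemble of ``n_trees`` trees (``mtry`` candidate
    features per split) is trained on all other subjects and predicts the
    held-out one.  Returns ``(predicted, accuracy, prob_matrix)`` where
    ``prob_matrix`` is a DataFrame of out-of-fold vote fractions with columns
    ``class_order``.
    """
    X = subjects.loc[:, list(features)].to_numpy(dtype=float)
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("labels length does not match subjects")
    present = pd.unique(y)
    if len(present) < 2:
        raise ValueError("need at least 2 classes for classification")
    counts = pd.Series(y).value_counts()
    if (counts == 1).any():
        warnings.warn(
            "classes with a single member: LOOCV folds may lack that class",
            stacklevel=2,
        )
    unknown = set(present) - set(class_order)
    if unknown:
        raise ValueError(f"labels outside class order: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    probs = np.zeros((n, len(class_order)))
    predicted = np.empty(n, dtype=object)
    idx_all = np.arange(n)
    for i in range(n):
        train = idx_all != i
        forest = _VoteForest(n_trees=n_trees, mtry=mtry, rng=rng)
        forest.fit(X[train], y[train])
        p = forest.vote_proba(X[i: i + 1], class_order)[0]
        probs[i] = p
        predicted[i] = class_order[int(np.argmax(p))]
    accuracy = float(np.mean(predicted == y))
    prob_matrix = pd.DataFrame(probs, index=subjects.index, columns=list(class_order))
    predicted = pd.Series(predicted, index=subjects.index, name="predicted")
    return predicted, accuracy, prob_matrix


def variable_importance(
    subjects: pd.DataFrame,
    labels,
    *,
    n_trees: int = 500,
    mtry: int = 2,
    features=FEATURE_COLUMNS,
    n_repeats: int = 10,
    seed=None,
):
    """Permutation importance: accuracy decrease (percentage points) per feature.

    A vote ensemble is trained on the full sample; each feature column is then
    shuffled ``n_repeats`` times and the mean drop in classification accuracy
    is reported on a 0-100 scale.
    """
    X = subjects.loc[:, list(features)].to_numpy(dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    class_order = tuple(pd.unique(y))
    forest = _VoteForest(n_trees=n_trees, mtry=mtry, rng=rng).fit(X, y)

    def acc(Xm):
        p = forest.vote_proba(Xm, class_order)
        pred = np.asarray(class_order, dtype=object)[np.argmax(p, axis=1)]
        return np.mean(pred == y)

    base = acc(X)
    out = {}
    for j, name in enumerate(features):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            drops.append(base - acc(Xp))
        out[name] = float(np.mean(drops) * 100.0)
    return out


@dataclass
class ReliabilityReport:
    cronbach_alpha: float
    n_items: int
    n_raters: int


def cronbach_alpha(ratings) -> ReliabilityReport:
    """Cronbach's alpha of a subjects x raters (or occasions) numeric matrix.

    alpha = k/(k-1) * (1 - sum(var(columns)) / var(row sums)), with sample
    variances (ddof=1).  Raises on zero total variance.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[1] < 2:
        raise ValueError("ratings must be a 2-D matrix with >= 2 columns")
    if R.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    k = R.shape[1]
    item_var = R.var(axis=0, ddof=1).sum()
    total_var = R.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of row sums: alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return ReliabilityReport(cronbach_alpha=float(alpha), n_items=R.shape[0], n_raters=k)


@dataclass
class DimensionScores:
    """Classical-MDS coordinates with eigenvalues and retained-variance fit."""

    coords: pd.DataFrame  # columns dim1..dimk
    eigenvalues: np.ndarray  # all eigenvalues, descending
    goodness_of_fit: float

    def __post_init__(self):
        lam = self.eigenvalues
        if np.any(np.diff(lam) > 1e-9):
            raise ValueError("eigenvalues must be non-increasing")


def classical_mds(prob: pd.DataFrame, k: int = 2) -> DimensionScores:
    """Classical (Torgerson) MDS of Euclidean distances between probability rows.

    Double-centers -0.5*D^2, takes the top-``k`` eigenvectors scaled by the
    square root of their eigenvalues, and reports goodness of fit
    (lambda_1 + ... + lambda_k) / sum(|lambda_i|).  Axis signs are fixed by
    making each dimension correlate positively with its highest-loading input
    column.
    """
    X = np.asarray(prob, dtype=float)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} subjects for k={k}")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    lam, vec = np.linalg.eigh(B)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = 1e-9 * max(1.0, float(np.abs(lam).max()))
    if np.any(lam[:k] < -tol):
        raise ValueError(f"fewer than k={k} non-negative eigenvalues")
    coords = vec[:, :k] * np.sqrt(np.clip(lam[:k], 0.0, None))
    # deterministic sign: align each axis with its highest-loading input column
    for j in range(k):
        cors = np.array([
            _safe_corr(coords[:, j], X[:, c]) for c in range(X.shape[1])
        ])
        c_best = int(np.argmax(np.abs(cors)))
        if cors[c_best] < 0:
            coords[:, j] = -coords[:, j]
    gof = float(lam[:k].sum() / np.abs(lam).sum())
    index = prob.index if isinstance(prob, pd.DataFrame) else pd.RangeIndex(n)
    frame = pd.DataFrame(coords, index=index, columns=[f"dim{j + 1}" for j in range(k)])
    return DimensionScores(coords=frame, eigenvalues=lam, goodness_of_fit=gof)


def _safe_corr(a, b):
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def dimension_anova(dims: DimensionScores, labels):
    """One-way ANOVA per MDS dimension over groups, with Tukey HSD post-hocs.

    Returns a dict ``{dimension: {"F", "df", "p", "tukey": {(g1, g2): p}}}``.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for col in dims.coords.columns:
        v = dims.coords[col].to_numpy()
        samples = [v[labels == g] for g in groups]
        if any(len(s) < 2 for s in samples):
            raise ValueError("every group needs at least 2 members")
        F, p = stats.f_oneway(*samples)
        df = (len(groups) - 1, len(v) - len(groups))
        entry = {"F": float(F), "df": df, "p": float(p), "tukey": {}}
        if len(groups) > 2:
            res = stats.tukey_hsd(*samples)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    entry["tukey"][(groups[i], groups[j])] = float(res.pvalue[i, j])
        out[col] = entry
    return out
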