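"""Matching-quality bootstrap: repeated well-matched vs randomly matched
case-control resamples and their voxelwise t distributions.

Each replicate re-draws a valid unique pairing from the same subject set:
the well-matched condition shuffles case-control assignment within the
coarsened site x brain-size strata, the random condition pairs cases with
controls uniformly across sites.  Differences between the two conditions'
t-score distributions therefore reflect match quality alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import matching
from .vbm.stats import one_sample_t, pair_differences

__all__ = ["BootstrapSummary", "run_bootstrap", "balance_check_bootstrap"]

CONDITIONS = ("well", "random")
BALANCE_VARS = ("gm_volume", "wm_volume", "age")


@dataclass
class BootstrapSummary:
    mean_t: dict                 # condition -> mean t map over replicates
    pooled_t: dict               # condition -> {roi name -> (B,) ROI-mean t}
    balance_p: dict              # condition -> {var -> (B,) paired-t p-values}
    B: int
    t_threshold: float
    seed: object
    mask: np.ndarray = field(repr=False, default=None)
    pairings: dict | None = None  # condition -> list of per-replicate pair lists

    def thresholded_mean(self, condition) -> np.ndarray:
        out = self.mean_t[condition].copy()
        out[out < self.t_threshold] = 0.0
        return out


def _well_matched_replicate(strata, frame, rng):
    rows = []
    for st in strata:
        members = frame.loc[st.member_ids]
        cases = list(members.loc[members["is_case"], "subject_id"])
        controls = list(members.loc[~members["is_case"], "subject_id"])
        rng.shuffle(cases)
        rng.shuffle(controls)
        for c, k in zip(cases, controls):
            rows.append((c, k))
    return rows


def _random_replicate(case_ids, control_ids, rng):
    n = min(len(case_ids), len(control_ids))
    cs = list(rng.permutation(case_ids))[:n]
    ks = list(rng.permutation(control_ids))[:n]
    return list(zip(cs, ks))


def run_bootstrap(
    subjects: pd.DataFrame,
    volumes,
    subject_ids,
    *,
    B: int = 1000,
    seed=None,
    rois: dict | None = None,
    t_threshold: float = 2.87,
    mask=None,
    strata=None,
    keep_pairings: bool = False,
) -> BootstrapSummary:
    """B well-matched and B random re-pairings of the same subjects.

    ``volumes`` is an adjusted (residualized) stack aligned with
    ``subject_ids``.  Per replicate the one-sample t map of the pair
    differences is computed; per ROI (name -> boolean grid) the ROI-mean t is
    recorded; paired-t balance p-values for gray/white volume and age are kept
    for :func:`balance_check_bootstrap`.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    Y = np.asarray(volumes, dtype=float)
    frame = subjects.set_index("subject_id", drop=False)
    frame["is_case"] = frame["is_case"].astype(bool)
    if strata is None:
        strata = matching.stratify(subjects)
    case_ids = list(frame.loc[frame["is_case"], "subject_id"])
    control_ids = list(frame.loc[~frame["is_case"], "subject_id"])
    rng = np.random.default_rng(seed)
    if mask is None:
        mask = np.ones(Y.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    rois = rois or {}
    for name, roi in rois.items():
        if not np.asarray(roi, dtype=bool).any():
            raise ValueError(f"ROI {name!r} is empty")

    mean_t = {c: np.zeros(Y.shape[1:]) for c in CONDITIONS}
    pooled = {c: {name: np.empty(B) for name in rois} for c in CONDITIONS}
    balance = {c: {v: np.empty(B) for v in BALANCE_VARS} for c in CONDITIONS}
    pairings = {c: [] for c in CONDITIONS} if keep_pairings else None

    for b in range(B):
        reps = {
            "well": _well_matched_replicate(strata, frame, rng),
            "random": _random_replicate(case_ids, control_ids, rng),
        }
        # equalize pair counts so conditions differ in match quality only
        n_common = min(len(v) for v in reps.values())
        for cond, pair_rows in reps.items():
            if len(pair_rows) > n_common:
                keep = rng.choice(len(pair_rows), size=n_common, replace=False)
                reps[cond] = [pair_rows[i] for i in keep]
        for cond, pair_rows in reps.items():
            if pairings is not None:
                pairings[cond].append(list(pair_rows))
            pairs = pd.DataFrame(pair_rows, columns=["case_id", "control_id"])
            diffs = pair_differences(Y, pairs, subject_ids)
            tmap = one_sample_t(diffs, mask=mask).data
            mean_t[cond] += tmap
            for name, roi in rois.items():
                pooled[cond][name][b] = tmap[np.asarray(roi, dtype=bool)].mean()
            for var in BALANCE_VARS:
                d = (frame.loc[pairs["case_id"], var].to_numpy()
                     - frame.loc[pairs["control_id"], var].to_numpy())
                if np.allclose(d.var(ddof=1), 0.0):
                    balance[cond][var][b] = 1.0 if np.allclose(d, 0.0) else 0.0
                else:
                    balance[cond][var][b] = sps.ttest_1samp(d, 0.0).pvalue
    for cond in CONDITIONS:
        mean_t[cond] /= B
        mean_t[cond][~mask] = 0.0
    return BootstrapSummary(mean_t=mean_t, pooled_t=pooled, balance_p=balance,
                            B=B, t_threshold=t_threshold, seed=seed, mask=mask,
                            pairings=pairings)


def balance_check_bootstrap(summary: BootstrapSummary, threshold: float = 0.26):
    """Minimum / median balance p per condition and the fraction above threshold."""
    report = {}
    for cond, per_var in summary.balance_p.items():
        report[cond] = {}
        for var, ps in per_var.items():
            report[cond][var] = {
                "min_p": float(np.min(ps)),
                "median_p": float(np.median(ps)),
                "frac_above": float(np.mean(ps > threshold)),
            }
    return report
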