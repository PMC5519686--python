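"""Voxelwise statistics: residualization, difference images, t maps,
effect-size maps, ROI summaries, and correlation helpers.

Volume stacks are arrays of shape (n_subjects, nx, ny, nz); all operations
are vectorized over voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatMap",
    "residualize",
    "pair_differences",
    "one_sample_t",
    "two_sample_t",
    "cohens_d_maps",
    "roi_mean",
    "pearson_r",
]


@dataclass
class StatMap:
    """A per-voxel statistic grid with its mask and degrees of freedom."""

    data: np.ndarray
    mask: np.ndarray
    name: str
    df: int

    def masked(self) -> np.ndarray:
        return self.data[self.mask]


def _as_stack(volumes) -> np.ndarray:
    arr = np.asarray(volumes, dtype=float)
    if arr.ndim != 4:
        raise ValueError("expected a (n_subjects, nx, ny, nz) stack")
    return arr


def residualize(volumes, scores) -> np.ndarray:
    """Per-voxel OLS of intensity on (intercept, score); residual + grand mean.

    The voxelwise grand mean is restored so adjusted images stay on the
    Jacobian scale.  A constant score degrades to mean-centering (identity
    after mean restoration) with a warning.
    """
    Y = _as_stack(volumes)
    s = np.asarray(scores, dtype=float)
    n = Y.shape[0]
    if s.shape != (n,):
        raise ValueError("one score per volume is required")
    if n < 3:
        raise ValueError("need at least 3 subjects to residualize")
    flat = Y.reshape(n, -1)
    mean = flat.mean(axis=0)
    sc = s - s.mean()
    denom = (sc ** 2).sum()
    if denom == 0:
        warnings.warn("constant score: adjustment is mean-centering only",
                      stacklevel=2)
        return Y.copy()
    beta = (sc @ (flat - mean)) / denom
    adjusted = flat - np.outer(sc, beta)
    return adjusted.reshape(Y.shape)


def pair_differences(volumes, pairs: pd.DataFrame, subject_ids) -> np.ndarray:
    """Case-minus-control voxelwise differences, one volume per pair.

    ``subject_ids`` gives the row order of ``volumes``.
    """
    Y = _as_stack(volumes)
    index = {sid: i for i, sid in enumerate(subject_ids)}
    missing = [s for s in pd.concat([pairs["case_id"], pairs["control_id"]])
               if s not in index]
    if missing:
        raise ValueError(f"pairs reference subjects without volumes: {missing[:5]}")
    ca = [index[s] for s in pairs["case_id"]]
    co = [index[s] for s in pairs["control_id"]]
    return Y[ca] - Y[co]


def _t_from_moments(mean, var, n):
    """t = mean / sqrt(var/n) with the zero-variance convention:
    t = 0 where both mean and variance vanish, +/-inf where only variance does."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
        zero_var = var <= 0
        t = np.where(zero_var & (mean == 0), 0.0, t)
        t = np.where(zero_var & (mean != 0), np.sign(mean) * np.inf, t)
    return t


def one_sample_t(diffs, mask=None, name="one-sample t") -> StatMap:
    """Voxelwise one-sample t of difference volumes against zero; df = n - 1."""
    D = _as_stack(diffs)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 difference volumes")
    mean = D.mean(axis=0)
    var = D.var(axis=0, ddof=1)
    t = _t_from_moments(mean, var, n)
    if mask is None:
        mask = np.ones(t.shape, dtype=bool)
    return StatMap(data=t, mask=np.asarray(mask, dtype=bool), name=name, df=n - 1)


def two_sample_t(volumes, case_flags, mask=None, name="two-sample t") -> StatMap:
    """Voxelwise pooled-variance two-sample t (cases minus controls)."""
    Y = _as_stack(volumes)
    flags = np.asarray(case_flags, dtype=bool)
    n1, n0 = int(flags.sum()), int((~flags).sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 subjects per group")
    g1, g0 = Y[flags], Y[~flags]
    mean = g1.mean(axis=0) - g0.mean(axis=0)
    sp2 = ((n1 - 1) * g1.var(axis=0, ddof=1) + (n0 - 1) * g0.var(axis=0, ddof=1)) \
        / (n1 + n0 - 2)
    se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    t = _t_from_moments(mean, se2, 1.0)
    if mask is None:
        mask = np.ones(t.shape, dtype=bool)
    return StatMap(data=t, mask=np.asarray(mask, dtype=bool), name=name,
                   df=n1 + n0 - 2)


def cohens_d_maps(adjusted, pairs: pd.DataFrame, subject_ids, case_flags,
                  mask=None, bins=50):
    """Paired and unpaired Cohen's d maps plus a masked-voxel histogram summary.

    paired d = mean(diff)/sd(diff); unpaired d = (mean_case - mean_control) /
    pooled sd.  Zero-sd voxels are returned as NaN and counted in the summary.
    """
    Y = _as_stack(adjusted)
    D = pair_differences(Y, pairs, subject_ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_paired = D.mean(axis=0) / D.std(axis=0, ddof=1)
    flags = np.asarray(case_flags, dtype=bool)
    g1, g0 = Y[flags], Y[~flags]
    n1, n0 = g1.shape[0], g0.shape[0]
    sp = np.sqrt(((n1 - 1) * g1.var(axis=0, ddof=1)
                  + (n0 - 1) * g0.var(axis=0, ddof=1)) / (n1 + n0 - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d_unpaired = (g1.mean(axis=0) - g0.mean(axis=0)) / sp
    if mask is None:
        mask = np.ones(d_paired.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    summary = {}
    for label, dmap in (("paired", d_paired), ("unpaired", d_unpaired)):
        vals = dmap[mask]
        finite = vals[np.isfinite(vals)]
        counts, edges = np.histogram(finite, bins=bins)
        summary[label] = {
            "counts": counts, "bin_edges": edges,
            "median_abs_d": float(np.median(np.abs(finite))) if finite.size else np.nan,
            "n_flagged": int(np.sum(~np.isfinite(vals))),
        }
    return d_paired, d_unpaired, summary


def roi_mean(volumes, region_mask) -> np.ndarray:
    """Per-subject (or per-difference) mean over a voxel region."""
    Y = _as_stack(volumes)
    region = np.asarray(region_mask, dtype=bool)
    if region.shape != Y.shape[1:]:
        raise ValueError("region shape does not match the volume grid")
    if not region.any():
        raise ValueError("empty region")
    return Y[:, region].mean(axis=1)


def pearson_r(x, y):
    """Pearson correlation with df = n - 2 and a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), n - 2, float(res.pvalue)
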