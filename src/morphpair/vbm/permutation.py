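"""Permutation inference with TFCE and max-statistic familywise correction.

One-sample (paired-difference) designs use sign flipping; two-group designs
permute labels.  Each permutation recomputes the t map and its TFCE
enhancement, and the image-wide maximum enhanced statistic forms the null
distribution.  Corrected p(v) = (1 + #{perm max >= observed TFCE(v)}) /
(P + 1), so p >= 1/(P+1) and the identity permutation is counted.  With
<= 12 difference volumes all 2^n sign patterns are enumerated exactly and
p = #{max >= observed}/2^n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import StatMap, _t_from_moments
from .tfce import TfceParams, tfce

__all__ = ["PermutationResult", "permutation_fwe", "covariate_control"]

_EXHAUSTIVE_MAX_N = 12
_CHUNK = 64


@dataclass
class PermutationResult:
    """Observed maps, null max-TFCE distribution, and corrected p-values."""

    t_map: StatMap
    tfce_map: np.ndarray
    null_max: np.ndarray
    p_corrected: np.ndarray
    n_perm: int
    exhaustive: bool
    seed: object = None

    @property
    def min_p(self) -> float:
        return float(self.p_corrected[self.t_map.mask].min())

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return (self.p_corrected < alpha) & self.t_map.mask


def _sign_matrix_exhaustive(n: int) -> np.ndarray:
    codes = np.arange(2 ** n, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(n)[None, :]) & 1
    return 1.0 - 2.0 * bits  # identity pattern first (all +1)


def _one_sample_t_many(signs: np.ndarray, flat: np.ndarray, sumsq: np.ndarray):
    """t maps for many sign patterns at once. flat is (n, V)."""
    n = flat.shape[0]
    m = signs @ flat / n
    var = np.maximum(sumsq[None, :] / n - m ** 2, 0.0) * (n / (n - 1))
    return _t_from_moments(m, var, n)


def _two_sample_t_many(flag_rows: np.ndarray, flat: np.ndarray):
    """Pooled t maps for many binary label rows at once."""
    n = flat.shape[0]
    n1 = int(flag_rows[0].sum())
    n0 = n - n1
    s1 = flag_rows @ flat
    ss1 = flag_rows @ (flat ** 2)
    tot = flat.sum(axis=0)[None, :]
    tot2 = (flat ** 2).sum(axis=0)[None, :]
    s0, ss0 = tot - s1, tot2 - ss1
    m = s1 / n1 - s0 / n0
    sp2 = np.maximum(ss1 - s1 ** 2 / n1, 0.0) + np.maximum(ss0 - s0 ** 2 / n0, 0.0)
    sp2 /= (n - 2)
    se2 = sp2 * (1.0 / n1 + 1.0 / n0)
    return _t_from_moments(m, se2, 1.0)


def _embed(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    grid = np.zeros(mask.shape)
    grid[mask] = vals
    return grid


def permutation_fwe(
    volumes,
    *,
    design: str = "sign_flip",
    labels=None,
    mask=None,
    tfce_params: TfceParams = TfceParams(),
    n_perm: int = 1000,
    seed=None,
    tfce_engine: str = "numba",
) -> PermutationResult:
    """Max-TFCE permutation test with familywise error correction.

    ``design='sign_flip'``: ``volumes`` are difference images; the one-sample
    t map is recomputed under random (or exhaustive) sign flips.
    ``design='label_perm'``: ``volumes`` are subject images and ``labels``
    boolean case flags permuted between groups.
    """
    Y = np.asarray(volumes, dtype=float)
    if Y.ndim != 4:
        raise ValueError("expected a (n, nx, ny, nz) stack")
    n = Y.shape[0]
    if mask is None:
        mask = np.ones(Y.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flat = Y[:, mask]

    if design == "sign_flip":
        sumsq = (flat ** 2).sum(axis=0)
        exhaustive = n <= _EXHAUSTIVE_MAX_N or n_perm >= 2 ** n
        if not exhaustive and n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if exhaustive:
            signs = _sign_matrix_exhaustive(n)
        else:
            rng = np.random.default_rng(seed)
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_obs = _one_sample_t_many(np.ones((1, n)), flat, sumsq)[0]
        df = n - 1
        name = "one-sample t"

        def t_rows(block):
            return _one_sample_t_many(block, flat, sumsq)

        perm_rows = signs
    elif design == "label_perm":
        if labels is None:
            raise ValueError("label_perm requires case labels")
        flags = np.asarray(labels, dtype=float)
        if flags.shape != (n,):
            raise ValueError("one label per volume is required")
        exhaustive = False
        rng = np.random.default_rng(seed)
        perm_rows = np.stack([flags[rng.permutation(n)] for _ in range(n_perm)])
        t_obs = _two_sample_t_many(flags[None, :], flat)[0]
        df = n - 2
        name = "two-sample t"

        def t_rows(block):
            return _two_sample_t_many(block, flat)
    else:
        raise ValueError("design must be 'sign_flip' or 'label_perm'")

    tfce_obs = tfce(_embed(t_obs, mask), mask, tfce_params, engine=tfce_engine)
    null_max = np.empty(perm_rows.shape[0])
    for start in range(0, perm_rows.shape[0], _CHUNK):
        block = perm_rows[start: start + _CHUNK]
        t_block = t_rows(block)
        for j in range(t_block.shape[0]):
            enh = tfce(_embed(t_block[j], mask), mask, tfce_params,
                       engine=tfce_engine)
            null_max[start + j] = enh[mask].max() if mask.any() else 0.0

    obs_vals = tfce_obs[mask]
    sorted_null = np.sort(null_max)
    exceed = null_max.shape[0] - np.searchsorted(sorted_null, obs_vals, side="left")
    if exhaustive:
        p_vals = exceed / null_max.shape[0]  # identity is in the enumeration
    else:
        p_vals = (1.0 + exceed) / (null_max.shape[0] + 1.0)
    p_map = np.ones(mask.shape)
    p_map[mask] = p_vals
    t_grid = _embed(t_obs, mask)
    return PermutationResult(
        t_map=StatMap(data=t_grid, mask=mask, name=name, df=df),
        tfce_map=tfce_obs, null_max=null_max, p_corrected=p_map,
        n_perm=int(null_max.shape[0]), exhaustive=exhaustive, seed=seed)


def _coef_t_many(D_rows, X, pinv, jj, test_col):
    """t of one regression coefficient per voxel for many data matrices.

    D_rows: (B, n, V) stacks; X: (n, k) fixed design; pinv: (k, n); jj:
    (X'X)^-1 diagonal entry of the tested column.
    """
    B, n, V = D_rows.shape
    k = X.shape[1]
    beta = np.einsum("kn,bnv->bkv", pinv, D_rows)
    resid = D_rows - np.einsum("nk,bkv->bnv", X, beta)
    sigma2 = (resid ** 2).sum(axis=1) / (n - k)
    # voxels fitted exactly (residual at rounding level) are genuine zeros
    scale = (D_rows ** 2).mean(axis=1)
    sigma2 = np.where(sigma2 <= 1e-24 * (scale + 1e-300), 0.0, sigma2)
    se2 = sigma2 * jj
    b = beta[:, test_col, :]
    b = np.where(sigma2 == 0.0, np.where(np.abs(b) ** 2 <= 1e-24 * (scale + 1e-300),
                                         0.0, b), b)
    return _t_from_moments(b, se2, 1.0)


def covariate_control(
    diffs,
    covariate,
    *,
    mode: str = "slope",
    mask=None,
    tfce_params: TfceParams = TfceParams(),
    n_perm: int = 1000,
    seed=None,
    tfce_engine: str = "numba",
) -> PermutationResult:
    """Per-pair covariate model diff ~ b0 + b1*covariate with permutation FWE.

    ``mode='slope'`` tests b1 by the Freedman-Lane scheme (permute residuals
    of the intercept-only reduced model); ``mode='intercept'`` tests b0 by
    sign-flipping residuals of the slope-only reduced model.  TFCE and
    max-statistic correction follow :func:`permutation_fwe`.
    """
    D = np.asarray(diffs, dtype=float)
    if D.ndim != 4:
        raise ValueError("expected a (n_pairs, nx, ny, nz) stack")
    n = D.shape[0]
    c = np.asarray(covariate, dtype=float)
    if c.shape != (n,):
        raise ValueError("one covariate value per pair is required")
    if mode not in ("slope", "intercept"):
        raise ValueError("mode must be 'slope' or 'intercept'")
    if mode == "slope" and np.ptp(c) == 0:
        raise ValueError("constant covariate cannot be tested in slope mode")
    if mask is None:
        mask = np.ones(D.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    flat = D[:, mask]

    X = np.column_stack([np.ones(n), c])
    XtX_inv = np.linalg.inv(X.T @ X)
    pinv = XtX_inv @ X.T
    test_col = 1 if mode == "slope" else 0
    jj = XtX_inv[test_col, test_col]

    t_obs = _coef_t_many(flat[None], X, pinv, jj, test_col)[0]
    rng = np.random.default_rng(seed)

    if mode == "slope":
        fit_red = flat.mean(axis=0, keepdims=True)  # intercept-only reduced model
        resid_red = flat - fit_red
        perm_idx = np.stack([rng.permutation(n) for _ in range(n_perm)])

        def data_block(rows):
            return fit_red[None] + resid_red[rows]
        perm_rows = perm_idx
    else:
        denom = float(c @ c)
        if denom == 0:
            fit_red = np.zeros_like(flat)
        else:
            b = (c @ flat) / denom  # slope-only reduced model, no intercept
            fit_red = np.outer(c, b)
        resid_red = flat - fit_red
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

        def data_block(rows):
            return fit_red[None] + rows[:, :, None] * resid_red[None]
        perm_rows = signs

    tfce_obs = tfce(_embed(t_obs, mask), mask, tfce_params, engine=tfce_engine)
    null_max = np.empty(n_perm)
    for start in range(0, n_perm, _CHUNK):
        rows = perm_rows[start: start + _CHUNK]
        D_block = data_block(rows)
        t_block = _coef_t_many(D_block, X, pinv, jj, test_col)
        for j in range(t_block.shape[0]):
            enh = tfce(_embed(t_block[j], mask), mask, tfce_params,
                       engine=tfce_engine)
            null_max[start + j] = enh[mask].max()

    obs_vals = tfce_obs[mask]
    sorted_null = np.sort(null_max)
    exceed = n_perm - np.searchsorted(sorted_null, obs_vals, side="left")
    p_vals = (1.0 + exceed) / (n_perm + 1.0)
    p_map = np.ones(mask.shape)
    p_map[mask] = p_vals
    return PermutationResult(
        t_map=StatMap(data=_embed(t_obs, mask), mask=mask,
                      name=f"covariate {mode} t", df=n - 2),
        tfce_map=tfce_obs, null_max=null_max, p_corrected=p_map,
        n_perm=n_perm, exhaustive=False, seed=seed)
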