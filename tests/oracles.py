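"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: connected
components come straight from scipy.ndimage labeling per threshold, sign-flip
p-values from explicit enumeration, and the closed forms are written out
longhand.
"""

import itertools

import numpy as np
from scipy import ndimage


def tfce_bruteforce(data, H=2.0, E=0.5, n_steps=100, connectivity=26, dh=None):
    """Per-threshold connected-component summation of the TFCE integral."""
    pos = np.where(data > 0, data, 0.0)
    h_max = pos.max()
    out = np.zeros_like(pos)
    if h_max <= 0:
        return out
    adaptive = dh is None
    if adaptive:
        dh = h_max / n_steps
    else:
        n_steps = int(np.floor(h_max / dh + 1e-12))
    tol = 1e-12 * h_max  # same discretization convention as the implementation
    structure = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    for k in range(1, n_steps + 1):
        h = k * dh
        if adaptive and k == n_steps:
            h = h_max
        lab, n = ndimage.label(pos >= h - tol, structure=structure)
        for voxel in np.argwhere(lab > 0):
            i, j, m = voxel
            extent = np.sum(lab == lab[i, j, m])
            out[i, j, m] += extent ** E * h ** H * dh
    return out


def sign_flip_p_bruteforce(diffs, mask, tfce_fn):
    """Exhaustive sign-flip max-TFCE corrected p-map by direct enumeration."""
    n = diffs.shape[0]
    flat = diffs[:, mask]
    maxes = []
    t_obs = _t_1samp(flat)
    obs_tfce = tfce_fn(_embed(t_obs, mask))
    for signs in itertools.product((1.0, -1.0), repeat=n):
        t = _t_1samp(np.asarray(signs)[:, None] * flat)
        enh = tfce_fn(_embed(t, mask))
        maxes.append(enh[mask].max())
    maxes = np.asarray(maxes)
    obs_vals = obs_tfce[mask]
    p = np.array([(maxes >= v).mean() for v in obs_vals])
    p_map = np.ones(mask.shape)
    p_map[mask] = p
    return p_map


def _t_1samp(flat):
    n = flat.shape[0]
    m = flat.mean(axis=0)
    s = flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    t = np.where((s == 0) & (m == 0), 0.0, t)
    return t


def _embed(vals, mask):
    grid = np.zeros(mask.shape)
    grid[mask] = vals
    return grid


def cronbach_alpha_longhand(R):
    R = np.asarray(R, dtype=float)
    k = R.shape[1]
    sum_item_var = sum(np.var(R[:, j], ddof=1) for j in range(k))
    total = np.var(R.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - sum_item_var / total)


def yates_chi2_longhand(table):
    # sum over cells of (|O - E| - 0.5)^2 / E, with the textbook clamp when
    # |O - E| < 0.5 (the correction cannot overshoot past E)
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    return float(((adj ** 2) / exp).sum())


def pearson_p_longhand(r, n):
    from scipy import stats
    df = n - 2
    t = r * np.sqrt(df / (1 - r ** 2))
    return float(2 * stats.t.sf(abs(t), df))
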