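"""Threshold-free cluster enhancement on 3-D statistic grids.

For each voxel p, TFCE(p) = sum over thresholds h = dh, 2dh, ..., h_max of
e_h(p)^E * h^H * dh, where e_h(p) is the size of the connected component
containing p at threshold h.  Only the positive tail is enhanced; voxels with
statistic <= 0 map to 0.

Two engines are provided: a union-find pass over descending thresholds
(numba, default) and a per-threshold scipy.ndimage labeling loop.  They agree
to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage

__all__ = ["TfceParams", "tfce"]


@dataclass(frozen=True)
class TfceParams:
    """Enhancement parameters.

    ``dh=None`` uses an adaptive step of h_max / n_steps per map (the
    convention of the reference permutation tool).  H=2, E=0.5 and
    26-connectivity are the canonical defaults of the method.
    """

    H: float = 2.0
    E: float = 0.5
    dh: float | None = None
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.H <= 0 or self.E <= 0:
            raise ValueError("H and E must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


_NEIGHBOR_CACHE: dict = {}


def _neighbor_table(shape, connectivity):
    """Flat-index neighbor lookup (V, n_offsets), -1 past the boundary."""
    key = (tuple(shape), connectivity)
    cached = _NEIGHBOR_CACHE.get(key)
    if cached is not None:
        return cached
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    nx, ny, nz = shape
    idx = np.arange(nx * ny * nz, dtype=np.int64).reshape(shape)
    nbr = np.full((nx * ny * nz, len(offs)), -1, dtype=np.int64)
    for j, (dx, dy, dz) in enumerate(offs):
        sl = np.full(shape, -1, dtype=np.int64)
        xs = slice(max(0, dx), nx + min(0, dx))
        xd = slice(max(0, -dx), nx + min(0, -dx))
        ys = slice(max(0, dy), ny + min(0, dy))
        yd = slice(max(0, -dy), ny + min(0, -dy))
        zs = slice(max(0, dz), nz + min(0, dz))
        zd = slice(max(0, -dz), nz + min(0, -dz))
        sl[xd, yd, zd] = idx[xs, ys, zs]
        nbr[:, j] = sl.ravel()
    _NEIGHBOR_CACHE[key] = nbr
    return nbr


@njit(cache=True)
def _tfce_union_find(flat, order, nbr, thresholds, tol, dh, H, E):  # pragma: no cover
    V = flat.shape[0]
    out = np.zeros(V)
    parent = np.full(V, -1, np.int64)
    csize = np.zeros(V, np.int64)
    ptr = 0
    for k in range(thresholds.shape[0] - 1, -1, -1):
        h = thresholds[k] - tol
        while ptr < V and flat[order[ptr]] >= h:
            v = order[ptr]
            parent[v] = v
            csize[v] = 1
            for j in range(nbr.shape[1]):
                w = nbr[v, j]
                if w >= 0 and parent[w] >= 0:
                    rv = v
                    while parent[rv] != rv:
                        rv = parent[rv]
                    rw = w
                    while parent[rw] != rw:
                        rw = parent[rw]
                    if rv != rw:
                        if csize[rv] < csize[rw]:
                            rv, rw = rw, rv
                        parent[rw] = rv
                        csize[rv] += csize[rw]
            ptr += 1
        inc = (thresholds[k] ** H) * dh
        for i in range(ptr):
            v = order[i]
            r = v
            while parent[r] != r:
                r = parent[r]
            x = v
            while parent[x] != r:
                nxt = parent[x]
                parent[x] = r
                x = nxt
            out[v] += (csize[r] ** E) * inc
    return out


def _tfce_ndimage(pos, params: TfceParams, thresholds, tol, dh):
    st = _structure(params.connectivity)
    out = np.zeros_like(pos)
    for h in thresholds:
        lab, nlab = ndimage.label(pos >= h - tol, structure=st)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.ravel())
        sup = lab > 0
        out[sup] += sizes[lab[sup]] ** params.E * h ** params.H * dh
    return out


def tfce(stat: np.ndarray, mask: np.ndarray | None = None,
         params: TfceParams = TfceParams(), engine: str = "numba") -> np.ndarray:
    """Enhance the positive tail of a 3-D statistic grid."""
    stat = np.asarray(stat, dtype=float)
    if stat.ndim != 3:
        raise ValueError("expected a 3-D statistic grid")
    if not np.all(np.isfinite(stat[mask] if mask is not None else stat)):
        raise ValueError("non-finite values inside the mask")
    pos = np.where(stat > 0, stat, 0.0)
    if mask is not None:
        pos = np.where(mask, pos, 0.0)
    h_max = pos.max()
    if h_max <= 0:
        return np.zeros_like(pos)
    if params.dh is None:
        dh = h_max / params.n_steps
        n_steps = params.n_steps
    else:
        dh = params.dh
        n_steps = max(int(np.floor(h_max / dh + 1e-12)), 1)
    thresholds = dh * np.arange(1, n_steps + 1, dtype=float)
    if params.dh is None:
        thresholds[-1] = h_max  # exact top step regardless of float rounding
    tol = 1e-12 * h_max  # absorbs k*dh rounding at threshold/value ties
    if engine == "ndimage":
        return _tfce_ndimage(pos, params, thresholds, tol, dh)
    if engine != "numba":
        raise ValueError("engine must be 'numba' or 'ndimage'")
    flat = pos.ravel()
    order = np.argsort(flat, kind="stable")[::-1].copy()
    nbr = _neighbor_table(pos.shape, params.connectivity)
    out = _tfce_union_find(flat, order, nbr, thresholds, tol, float(dh),
                           float(params.H), float(params.E))
    return out.reshape(pos.shape)
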