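"""Connected suprathreshold clusters of corrected p maps."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .tfce import _structure

__all__ = ["extract_clusters"]

CLUSTER_COLUMNS = (
    "label", "n_voxels", "peak_i", "peak_j", "peak_k",
    "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat", "mean_stat", "min_p",
)


def extract_clusters(
    p_map: np.ndarray,
    stat_map: np.ndarray,
    *,
    mask=None,
    alpha: float = 0.05,
    connectivity: int = 26,
    affine=None,
) -> pd.DataFrame:
    """Connected components of {corrected p < alpha}, one row per cluster.

    Rows carry voxel count, the peak-statistic voxel (index and world mm via
    ``affine``), cluster-mean statistic, and minimum corrected p; sorted by
    size descending.  Empty if nothing survives.
    """
    p_map = np.asarray(p_map, dtype=float)
    stat_map = np.asarray(stat_map, dtype=float)
    if mask is None:
        mask = np.ones(p_map.shape, dtype=bool)
    sig = (p_map < alpha) & np.asarray(mask, dtype=bool)
    if affine is None:
        affine = np.eye(4)
    labeled, n_clusters = ndimage.label(sig, structure=_structure(connectivity))
    rows = []
    for lab in range(1, n_clusters + 1):
        sel = labeled == lab
        stats_in = stat_map[sel]
        idx = np.argwhere(sel)
        peak_local = int(np.argmax(stats_in))
        pi, pj, pk = idx[peak_local]
        world = affine @ np.array([pi, pj, pk, 1.0])
        rows.append({
            "label": lab,
            "n_voxels": int(sel.sum()),
            "peak_i": int(pi), "peak_j": int(pj), "peak_k": int(pk),
            "peak_x_mm": float(world[0]), "peak_y_mm": float(world[1]),
            "peak_z_mm": float(world[2]),
            "peak_stat": float(stats_in.max()),
            "mean_stat": float(stats_in.mean()),
            "min_p": float(p_map[sel].min()),
        })
    table = pd.DataFrame(rows, columns=list(CLUSTER_COLUMNS))
    return table.sort_values("n_voxels", ascending=False).reset_index(drop=True)
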