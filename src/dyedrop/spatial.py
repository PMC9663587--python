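"""Spatial nearest-neighbor analysis of S-phase cells.

Distinguishes clonal outgrowth (S-phase cells clustered in colonies) from
population-wide adaptation (S-phase cells interspersed among the rest):
for every S-phase cell we compute the Euclidean distance to its nearest
S-phase neighbor (d_SS) and to the nearest cell in any other phase
(d_SO). Clustered S cells give median(d_SS)/median(d_SO) well below 1; a
uniformly mixed population gives a ratio near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import ranksums

__all__ = ["nn_distances", "compare_distributions", "spatial_report"]


def nn_distances(
    xy: np.ndarray, is_s: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-S-cell nearest-neighbor distances within and across phases.

    Parameters
    ----------
    xy : (n, 2) array of coordinates in one declared unit.
    is_s : boolean mask marking S-phase cells.

    Returns
    -------
    d_ss : distance from each S cell to its nearest *other* S cell
        (empty, with flag ``too_few_s``, when fewer than 2 S cells).
    d_so : distance from each S cell to the nearest non-S cell
        (empty, with flag ``no_other_cells``, when no other cells exist).
    flags : list of degeneracy flags.
    """
    xy = np.asarray(xy, dtype=float)
    is_s = np.asarray(is_s, dtype=bool)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be an (n, 2) array")
    if not np.all(np.isfinite(xy)):
        raise ValueError("coordinates must be finite")
    s_pts = xy[is_s]
    o_pts = xy[~is_s]
    flags: list[str] = []

    if len(s_pts) >= 2:
        tree_s = cKDTree(s_pts)
        d, _ = tree_s.query(s_pts, k=2)
        d_ss = d[:, 1]  # k=1 is the point itself at distance 0
    else:
        d_ss = np.empty(0)
        flags.append("too_few_s")
    if len(o_pts) >= 1 and len(s_pts) >= 1:
        tree_o = cKDTree(o_pts)
        d_so, _ = tree_o.query(s_pts, k=1)
    else:
        d_so = np.empty(0)
        if len(s_pts) >= 1:
            flags.append("no_other_cells")
    return d_ss, d_so, flags


def compare_distributions(
    d_ss: np.ndarray, d_so: np.ndarray
) -> tuple[float, float, float]:
    """Rank-sum comparison of the two distance distributions.

    Returns ``(statistic, p_value, median_ratio)`` with median_ratio =
    median(d_SS)/median(d_SO); values < 1 indicate S-phase clustering.
    Empty input yields NaNs rather than an exception.
    """
    d_ss = np.asarray(d_ss, dtype=float)
    d_so = np.asarray(d_so, dtype=float)
    if d_ss.size == 0 or d_so.size == 0:
        return float("nan"), float("nan"), float("nan")
    stat, p = ranksums(d_ss, d_so)
    med_so = np.median(d_so)
    ratio = float(np.median(d_ss) / med_so) if med_so > 0 else float("inf")
    return float(stat), float(p), ratio


@dataclass
class WellSpatialResult:
    well: str
    n_s: int
    median_d_ss: float
    median_d_so: float
    median_ratio: float
    statistic: float
    p_value: float
    flags: str


def spatial_report(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-well nearest-neighbor report from a labeled cell table.

    Expects columns ``well, x, y, phase`` (from the gating step); fields
    are pooled within a well, assuming coordinates are well-global.
    """
    rows = []
    for well, grp in labels.groupby("well"):
        xy = grp[["x", "y"]].to_numpy()
        is_s = (grp["phase"] == "S").to_numpy()
        d_ss, d_so, flags = nn_distances(xy, is_s)
        stat, p, ratio = compare_distributions(d_ss, d_so)
        rows.append(
            WellSpatialResult(
                well=well,
                n_s=int(is_s.sum()),
                median_d_ss=float(np.median(d_ss)) if d_ss.size else float("nan"),
                median_d_so=float(np.median(d_so)) if d_so.size else float("nan"),
                median_ratio=ratio,
                statistic=stat,
                p_value=p,
                flags=";".join(flags),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
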