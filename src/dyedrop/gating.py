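"""Single-cell viability and cell-cycle gating from stain intensities.

Each channel (LDR dead-cell stain, EdU S-phase label, pH3 mitosis marker)
is background-corrected by subtracting the perinuclear ring intensity,
log10-transformed, smoothed with a Gaussian kernel density estimate, and
thresholded at the global minimum of the KDE between its two most
prominent peaks. DNA content (mean nuclear Hoechst intensity x nuclear
area) is gated into sub-G1 / G1 / S-dropout / G2 / beyond-G2 windows
anchored on the G1 and G2 = 2xG1 modes.

Classification precedence per cell: corpse (LDR+ with essentially no
Hoechst signal) > dead (LDR+) > M (pH3+) > S (EdU+) > DNA-content window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "GateThresholds",
    "correct_background",
    "dna_content",
    "find_cutoff",
    "find_dna_windows",
    "classify_cells",
    "summarize_well",
]

CHANNELS = ("ldr", "edu", "ph3")

#: live-cell phase labels in reporting order
PHASES = ("subG1", "G1", "S", "G2", "S_dropout", "beyondG2", "M")

_GRID_POINTS = 1024
_MIN_CELLS = 200
_PROMINENCE_FRAC = 0.01
LOG_FLOOR = 1.0  # a.u.; corrected intensities are floored here before log10


@dataclass
class GateThresholds:
    """Log10 channel cutoffs plus DNA-content window edges (log10 a.u.)."""

    ldr_cutoff: float
    edu_cutoff: float
    ph3_cutoff: float
    dna_g1_low: float
    dna_g1_high: float
    dna_g2_low: float
    dna_g2_high: float
    corpse_floor: float  # linear a.u.
    provenance: str = "pooled"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.dna_g1_low < self.dna_g1_high <= self.dna_g2_low < self.dna_g2_high
        ):
            raise ValueError("DNA windows must be ordered g1_low < g1_high <= g2_low < g2_high")

    def to_keyvalues(self, path) -> None:
        with open(path, "w") as fh:
            for k in (
                "ldr_cutoff", "edu_cutoff", "ph3_cutoff",
                "dna_g1_low", "dna_g1_high", "dna_g2_low", "dna_g2_high",
                "corpse_floor",
            ):
                fh.write(f"{k}={getattr(self, k):.6g}\n")
            fh.write(f"provenance={self.provenance}\n")
            fh.write(f"flags={';'.join(self.flags)}\n")


def correct_background(
    rec: pd.DataFrame | pd.Series, channel: str, floor: float = LOG_FLOOR
) -> np.ndarray | float:
    """Ring-subtracted nuclear intensity, floored so log10 is defined.

    ``corrected = max(nuclear_mean - ring_mean, floor)``.
    """
    channel = channel.lower()
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    nuc = rec[f"{channel}_nuclear"]
    ring = rec[f"{channel}_ring"]
    corrected = np.maximum(np.asarray(nuc, dtype=float) - np.asarray(ring, dtype=float), floor)
    return float(corrected) if np.ndim(corrected) == 0 else corrected


def dna_content(rec: pd.DataFrame | pd.Series) -> np.ndarray | float:
    """DNA content = mean nuclear Hoechst intensity x nuclear area (a.u.)."""
    area = np.asarray(rec["nuclear_area"], dtype=float)
    if np.any(area <= 0):
        raise ValueError("nuclear_area must be > 0")
    out = np.asarray(rec["hoechst_nuclear"], dtype=float) * area
    return float(out) if np.ndim(out) == 0 else out


def _kde_grid(logv: np.ndarray, pad: float = 0.25):
    """KDE of log10 values on a fixed grid (Silverman bandwidth)."""
    kde = gaussian_kde(logv, bw_method="silverman")
    lo, hi = logv.min() - pad, logv.max() + pad
    grid = np.linspace(lo, hi, _GRID_POINTS)
    return grid, kde(grid)


def _top_two_peaks(grid: np.ndarray, dens: np.ndarray):
    """Indices of the two most prominent KDE peaks, or fewer if unimodal."""
    peaks, props = find_peaks(dens, prominence=_PROMINENCE_FRAC * dens.max())
    if len(peaks) == 0:
        # monotone or edge-peaked density: treat the max as the single mode
        return [int(np.argmax(dens))], []
    order = np.argsort(props["prominences"])[::-1]
    top = sorted(peaks[order[:2]])
    return ([int(top[0])], []) if len(top) == 1 else ([int(top[0])], [int(top[1])])


def find_cutoff(
    values: np.ndarray, channel: str = "", min_cells: int = _MIN_CELLS
) -> tuple[float, list[str]]:
    """Log10 cutoff at the KDE global minimum between the two main peaks.

    Returns ``(cutoff, flags)``. Unimodal distributions fall back to
    ``mode + 2 * 1.4826 * MAD`` of the log10 values with an
    ``unimodal_fallback`` flag; degenerate (all-identical) input gets the
    same treatment. Fewer than ``min_cells`` values adds ``too_few_cells``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty intensity vector")
    flags: list[str] = []
    if values.size < min_cells:
        flags.append("too_few_cells")
    logv = np.log10(np.maximum(values, LOG_FLOOR))
    if np.ptp(logv) == 0:
        flags.append("unimodal_fallback")
        return float(logv[0]), flags
    grid, dens = _kde_grid(logv)
    first, second = _top_two_peaks(grid, dens)
    if not second:
        mode = grid[first[0]]
        mad = np.median(np.abs(logv - np.median(logv)))
        flags.append("unimodal_fallback")
        return float(mode + 2.0 * 1.4826 * mad), flags
    i, j = first[0], second[0]
    between = slice(i + 1, j)
    cutoff = grid[i + 1 + int(np.argmin(dens[between]))]
    return float(cutoff), flags


def find_dna_windows(
    dna: np.ndarray, w: float = 0.15, min_cells: int = _MIN_CELLS
) -> tuple[tuple[float, float, float, float], list[str]]:
    """DNA-content window edges (log10 a.u.) from LDR-negative cells.

    The G1 mode is the highest KDE peak of log10(DNA); the G2 mode is the
    detected peak nearest G1 + log10(2), imputed at exactly G1 + log10(2)
    when absent (flag ``g2_imputed``). The G1/G2 boundary is the KDE
    minimum between the modes (midpoint if none); the outer edges sit
    ``w`` log10 units beyond each mode.
    """
    dna = np.asarray(dna, dtype=float)
    if dna.size < min_cells:
        raise ValueError(f"need >= {min_cells} cells to fit DNA windows, got {dna.size}")
    flags: list[str] = []
    logd = np.log10(np.maximum(dna, LOG_FLOOR))
    if np.ptp(logd) == 0:
        raise ValueError("degenerate DNA distribution: all values identical")
    grid, dens = _kde_grid(logd, pad=0.4)
    peaks, props = find_peaks(dens, prominence=_PROMINENCE_FRAC * dens.max())
    if len(peaks) == 0:
        raise ValueError("no peaks found in DNA-content density")
    # G1 = highest peak; G2 = peak nearest G1 + log10(2) among the others
    g1_idx = peaks[int(np.argmax(dens[peaks]))]
    g1_mode = grid[g1_idx]
    target = g1_mode + np.log10(2.0)
    others = [p for p in peaks if p != g1_idx and grid[p] > g1_mode]
    if others:
        g2_idx = min(others, key=lambda p: abs(grid[p] - target))
        g2_mode = grid[g2_idx]
        if abs(g2_mode - target) > 0.2:  # not a plausible 4N peak
            g2_mode = target
            flags.append("g2_imputed")
        else:
            between = dens[g1_idx + 1 : g2_idx]
            boundary = (
                grid[g1_idx + 1 + int(np.argmin(between))]
                if between.size
                else 0.5 * (g1_mode + g2_mode)
            )
            return (
                (g1_mode - w, boundary, boundary, g2_mode + w),
                flags,
            )
    else:
        g2_mode = target
        flags.append("g2_imputed")
    boundary = 0.5 * (g1_mode + g2_mode)
    return (g1_mode - w, boundary, boundary, g2_mode + w), flags


def fit_thresholds(
    cells: pd.DataFrame,
    corpse_floor_frac: float = 0.01,
    provenance: str = "pooled",
) -> GateThresholds:
    """Derive all gate thresholds from a (pooled) single-cell table."""
    flags: list[str] = []
    cutoffs = {}
    for ch in CHANNELS:
        cut, f = find_cutoff(correct_background(cells, ch), ch)
        cutoffs[ch] = cut
        flags.extend(f"{ch}:{x}" for x in f)
    dna = dna_content(cells)
    ldr_neg = np.log10(np.maximum(correct_background(cells, "ldr"), LOG_FLOOR)) <= cutoffs["ldr"]
    (g1_low, g1_high, g2_low, g2_high), f = find_dna_windows(dna[ldr_neg])
    flags.extend(f"dna:{x}" for x in f)
    corpse_floor = corpse_floor_frac * 10.0 ** (g1_low + 0.15)  # frac of G1 mode
    return GateThresholds(
        ldr_cutoff=cutoffs["ldr"],
        edu_cutoff=cutoffs["edu"],
        ph3_cutoff=cutoffs["ph3"],
        dna_g1_low=g1_low,
        dna_g1_high=g1_high,
        dna_g2_low=g2_low,
        dna_g2_high=g2_high,
        corpse_floor=corpse_floor,
        provenance=provenance,
        flags=flags,
    )


def classify_cells(cells: pd.DataFrame, thr: GateThresholds) -> pd.DataFrame:
    """Assign a (viability, phase) label pair to every cell.

    Decision order: (1) corpse if LDR above cutoff and DNA content below
    the corpse floor; (2) dead if LDR above cutoff; otherwise alive and
    (3) M if pH3+, (4) S if EdU+, then by DNA content: (5) subG1,
    (6) G1, (7) S_dropout, (8) G2, (9) beyondG2.
    """
    required = ["nuclear_area", "hoechst_nuclear"] + [
        f"{ch}_{part}" for ch in CHANNELS for part in ("nuclear", "ring")
    ]
    missing = [c for c in required if c not in cells.columns]
    if missing:
        raise KeyError(f"missing feature columns: {missing}")

    n = len(cells)
    viability = np.full(n, "alive", dtype=object)
    phase = np.full(n, "none", dtype=object)
    if n == 0:
        out = cells.copy()
        out["viability"], out["phase"] = viability, phase
        return out

    log = lambda v: np.log10(np.maximum(v, LOG_FLOOR))
    ldr = log(correct_background(cells, "ldr"))
    edu = log(correct_background(cells, "edu"))
    ph3 = log(correct_background(cells, "ph3"))
    dna = dna_content(cells)
    logdna = log(dna)

    ldr_pos = ldr > thr.ldr_cutoff
    corpse = ldr_pos & (dna < thr.corpse_floor)
    dead = ldr_pos & ~corpse
    viability[corpse] = "corpse"
    viability[dead] = "dead"

    alive = ~ldr_pos
    m = alive & (ph3 > thr.ph3_cutoff)
    s = alive & ~m & (edu > thr.edu_cutoff)
    rest = alive & ~m & ~s
    phase[m] = "M"
    phase[s] = "S"
    phase[rest & (logdna < thr.dna_g1_low)] = "subG1"
    phase[rest & (logdna >= thr.dna_g1_low) & (logdna <= thr.dna_g1_high)] = "G1"
    phase[rest & (logdna > thr.dna_g1_high) & (logdna < thr.dna_g2_low)] = "S_dropout"
    phase[rest & (logdna >= thr.dna_g2_low) & (logdna <= thr.dna_g2_high)] = "G2"
    phase[rest & (logdna > thr.dna_g2_high)] = "beyondG2"

    out = cells.copy()
    out["viability"] = viability
    out["phase"] = phase
    return out


def summarize_well(labels: pd.DataFrame) -> pd.Series:
    """Per-well counts and live-cell phase fractions.

    ``dead`` includes corpses; fractions are over live cells and are NaN
    (with an ``empty_live`` flag) when no cell is alive.
    """
    n = len(labels)
    alive = labels["viability"] == "alive"
    corpse = int((labels["viability"] == "corpse").sum())
    dead = int((labels["viability"] == "dead").sum()) + corpse
    live = int(alive.sum())
    row: dict = {"total": n, "live": live, "dead": dead, "corpse": corpse}
    flags = []
    if n == 0:
        flags.append("empty_well")
    for ph in PHASES:
        cnt = int((labels.loc[alive, "phase"] == ph).sum())
        row[f"n_{ph}"] = cnt
        row[f"f_{ph}"] = cnt / live if live > 0 else np.nan
    if live == 0 and n > 0:
        flags.append("empty_live")
    row["flags"] = ";".join(flags)
    return pd.Series(row)
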