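"""Growth-rate inhibition (GR) dose-response metrics.

GR values normalize a drug response by the growth rate of the untreated
control, removing the division-rate bias that confounds relative-viability
metrics (IC50/Emax) across cell lines:

    GR(c) = 2^( log2(x(c)/x0) / log2(x_ctrl/x0) ) - 1

with x0 the viable count on the time-zero plate, x_ctrl the end-point
negative-control count and x(c) the treated count. GR = 1 means
unperturbed growth, 0 no net growth, negative values net cell loss.

A sigmoid GR(c) = GR_inf + (1 - GR_inf) / (1 + (c/GEC50)^h) is fitted by
bounded least squares, and the standard metrics derived: GR50 (where the
curve crosses 0.5), GEC50 (half-maximal effect), GRmax (measured GR at
the top dose), h_GR (Hill slope) and GR_AOC (area over the curve on the
log10-dose axis). QC flags mark designs with too few controls, an
incomplete dose range, a poor fit, or a fit stuck at a parameter bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "GRCurveFit",
    "QCFlags",
    "gr_value",
    "growth_rate",
    "fit_gr_curve",
    "gr50_from_fit",
    "gr_aoc",
    "qc_flags",
    "sphase_duration",
]

PSEUDOCOUNT = 0.5  # cells; substituted for x = 0 (total kill) wells

GR_INF_BOUNDS = (-1.0, 1.0)
HILL_BOUNDS = (0.1, 5.0)


def gr_value(x0: float, x_ctrl: float, x: float) -> tuple[float, list[str]]:
    """GR value for one condition; returns ``(gr, flags)``.

    ``x = 0`` wells are floored at a 0.5-cell pseudo-count (flag
    ``zero_count``) so total kill maps to a large negative GR rather than
    NaN. A non-growing control (``x_ctrl <= x0``) yields NaN with flag
    ``nongrowing_control``.
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    flags: list[str] = []
    if x_ctrl <= x0:
        return float("nan"), ["nongrowing_control"]
    if x <= 0:
        x = PSEUDOCOUNT
        flags.append("zero_count")
    gr = 2.0 ** (math.log2(x / x0) / math.log2(x_ctrl / x0)) - 1.0
    return gr, flags


def growth_rate(x0: float, x_ctrl: float, t_days: float) -> float:
    """Control growth rate in doublings/day: log2(x_ctrl/x0) / t."""
    if t_days <= 0:
        raise ValueError("t must be > 0 days")
    if x_ctrl <= 0 or x0 <= 0:
        raise ValueError("counts must be > 0")
    return math.log2(x_ctrl / x0) / t_days


def sphase_duration(f_s: float, doubling_time_h: float) -> float:
    """First-order S-phase duration estimate: f_S x doubling time (hours).

    Assumes the S fraction measured from a short EdU pulse approximates
    the fraction of the cycle spent in S; the exponential age structure of
    a growing culture makes this a slight underestimate.
    """
    if not 0.0 <= f_s <= 1.0:
        raise ValueError("f_S must be in [0, 1]")
    if doubling_time_h <= 0:
        raise ValueError("doubling_time must be > 0")
    return f_s * doubling_time_h


def _sigmoid(c, gr_inf, log10_gec50, h):
    return gr_inf + (1.0 - gr_inf) / (1.0 + (c / 10.0**log10_gec50) ** h)


@dataclass
class GRCurveFit:
    """Fitted GR dose-response sigmoid and its derived metrics."""

    gr_inf: float
    gec50: float  # uM; +inf for flat fits
    h_gr: float
    gr50: float  # uM; +inf when GR never crosses 0.5
    gr_max: float  # mean measured GR at the highest tested dose
    gr_aoc: float
    rmse: float
    flat_fit: bool
    n_doses: int
    doses: np.ndarray = field(repr=False, default=None)
    flags: list[str] = field(default_factory=list)

    def predict(self, c: np.ndarray) -> np.ndarray:
        if self.flat_fit:
            return np.full_like(np.asarray(c, dtype=float), self.gr_inf)
        return _sigmoid(np.asarray(c, dtype=float), self.gr_inf, np.log10(self.gec50), self.h_gr)


def gr50_from_fit(gr_inf: float, gec50: float, h: float) -> float:
    """Concentration at which the fitted sigmoid crosses GR = 0.5.

    Closed form: GEC50 * ((1 - GR_inf)/(0.5 - GR_inf) - 1)^(1/h); +inf when
    the asymptote never reaches 0.5.
    """
    if gr_inf >= 0.5 or not np.isfinite(gec50):
        return float("inf")
    ratio = (1.0 - gr_inf) / (0.5 - gr_inf) - 1.0
    return gec50 * ratio ** (1.0 / h)


def _fit_sigmoid_bounded(
    doses: np.ndarray,
    values: np.ndarray,
    inf_bounds: tuple[float, float],
    rising: bool = False,
) -> tuple[np.ndarray, float, bool, bool]:
    """Bounded multi-start least squares of the 3-parameter Hill sigmoid.

    Returns (params = [inf, log10_mid, h], rmse, flat, at_bound). ``rising``
    selects the increasing-Hill form used for the cytotoxic component.
    """
    lo_c, hi_c = doses[doses > 0].min(), doses.max()
    log_lo, log_hi = math.log10(lo_c) - 2.0, math.log10(hi_c) + 2.0
    bounds = (
        [inf_bounds[0], log_lo, HILL_BOUNDS[0]],
        [inf_bounds[1], log_hi, HILL_BOUNDS[1]],
    )

    def model(c, inf, log_mid, h):
        frac = 1.0 / (1.0 + (c / 10.0**log_mid) ** h)
        return inf * (1.0 - frac) if rising else inf + (1.0 - inf) * frac

    mid_guess = math.log10(math.sqrt(lo_c * hi_c))
    inf_guess = float(np.clip(values[np.argsort(doses)][-1], *inf_bounds))
    starts = [
        (inf_guess, mid_guess, 1.0),
        (inf_guess, log_lo + 1.0, 2.0),
        (inf_guess, log_hi - 1.0, 0.5),
    ]
    best, best_sse = None, np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    model, doses, values, p0=np.clip(p0, *bounds), bounds=bounds,
                    maxfev=10000,
                )
        except RuntimeError:
            continue
        sse = float(np.sum((model(doses, *popt) - values) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:  # pragma: no cover - curve_fit with bounds rarely fails outright
        best = np.array([np.mean(values), mid_guess, 1.0])
        best_sse = float(np.sum((values - values.mean()) ** 2))

    n = len(values)
    rmse = math.sqrt(best_sse / n)
    # F-test: sigmoid (3 params) vs constant (1 param)
    sse_const = float(np.sum((values - values.mean()) ** 2))
    df1, df2 = 2, n - 3
    flat = True
    if df2 > 0 and best_sse > 0:
        f_stat = ((sse_const - best_sse) / df1) / (best_sse / df2)
        flat = stats.f.sf(f_stat, df1, df2) > 0.05
    elif best_sse == 0 and sse_const > 0:
        flat = False
    at_bound = bool(
        np.isclose(best[1], log_lo, atol=1e-6) or np.isclose(best[1], log_hi, atol=1e-6)
    )
    return np.asarray(best), rmse, flat, at_bound


def fit_gr_curve(doses, gr_values) -> GRCurveFit:
    """Fit the GR sigmoid to per-dose GR values (replicates allowed).

    Requires >= 5 distinct positive doses. Non-finite GR values are
    dropped with a warning. If an F-test cannot reject a constant model at
    alpha = 0.05 the fit is flagged flat and GEC50/GR50 report +inf.
    """
    doses = np.asarray(doses, dtype=float)
    gr_values = np.asarray(gr_values, dtype=float)
    keep = np.isfinite(gr_values) & np.isfinite(doses) & (doses > 0)
    if keep.sum() < len(gr_values):
        warnings.warn(f"dropping {len(gr_values) - int(keep.sum())} non-finite GR values")
    doses, gr_values = doses[keep], gr_values[keep]
    n_doses = len(np.unique(doses))
    if n_doses < 5:
        raise ValueError(f"need >= 5 distinct doses, got {n_doses}")

    flags: list[str] = []
    params, rmse, flat, at_bound = _fit_sigmoid_bounded(doses, gr_values, GR_INF_BOUNDS)
    top = doses.max()
    gr_max = float(np.mean(gr_values[doses == top]))
    if flat:
        gr_inf = float(np.mean(gr_values))
        gec50, h, gr50 = float("inf"), float("nan"), float("inf")
        aoc_curve = np.full_like(doses, gr_inf)
        flags.append("flat_fit")
    else:
        gr_inf, h = float(params[0]), float(params[2])
        gec50 = float(10.0 ** params[1])
        gr50 = gr50_from_fit(gr_inf, gec50, h)
        aoc_curve = _sigmoid(doses, gr_inf, params[1], h)
        if at_bound:
            flags.append("gec50_at_bound")
    aoc = gr_aoc(doses, aoc_curve)
    return GRCurveFit(
        gr_inf=gr_inf, gec50=gec50, h_gr=h, gr50=gr50, gr_max=gr_max,
        gr_aoc=aoc, rmse=rmse, flat_fit=flat, n_doses=n_doses,
        doses=np.unique(doses), flags=flags,
    )


def gr_aoc(doses, gr_values) -> float:
    """Area over the GR curve on the log10-dose axis, range-normalized.

    Trapezoidal integral of (1 - GR) over log10(c) divided by the log10
    dose-range width: 0 for GR = 1 everywhere, 1 for GR = 0, 2 for GR = -1.
    Replicate doses are averaged first.
    """
    doses = np.asarray(doses, dtype=float)
    gr_values = np.asarray(gr_values, dtype=float)
    uniq = np.unique(doses)
    if len(uniq) < 2:
        raise ValueError("need >= 2 distinct doses for GR_AOC")
    means = np.array([gr_values[doses == u].mean() for u in uniq])
    logc = np.log10(uniq)
    width = logc[-1] - logc[0]
    return float(np.trapezoid(1.0 - means, logc) / width)


@dataclass
class QCFlags:
    """Experimental-design and fit-quality alerts for one condition."""

    too_few_controls: bool = False
    dose_range_incomplete: bool = False
    poor_fit: bool = False
    gec50_at_bound: bool = False
    unimodal_fallback: bool = False

    def any(self) -> bool:
        return any(vars(self).values())

    def tokens(self) -> str:
        return ";".join(k for k, v in vars(self).items() if v)


def qc_flags(
    n_controls: int,
    fit: GRCurveFit,
    rmse_threshold: float = 0.15,
    min_controls: int = 3,
    unimodal_fallback: bool = False,
) -> QCFlags:
    """Derive QC flags from the plate design and a fitted GR curve."""
    dmin, dmax = float(fit.doses.min()), float(fit.doses.max())
    incomplete = False
    if not fit.flat_fit:
        gr_at_max = float(fit.predict(np.array([dmax]))[0])
        incomplete = not (dmin <= fit.gec50 <= dmax) or gr_at_max > 0.5
    return QCFlags(
        too_few_controls=n_controls < min_controls,
        dose_range_incomplete=incomplete,
        poor_fit=fit.rmse > rmse_threshold,
        gec50_at_bound="gec50_at_bound" in fit.flags,
        unimodal_fallback=unimodal_fallback,
    )
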