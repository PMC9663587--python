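"""Cytostatic/cytotoxic decomposition of drug responses.

A simple exponential birth-death model of the live (``x``) and cumulative
dead (``d``) populations,

    dx/dt = ln(2) (ks - kd) x,      dd/dt = ln(2) kd x,

is solved for the constant per-day division rate ``ks`` and death rate
``kd`` from the two observed time points (time-zero and end-of-assay
counts):

    ks = (1/t) (1 + dd/dx) log2(x/x0),   kd = (1/t) (dd/dx) log2(x/x0)

with dd = d - d0 (clamped to at least 1 cell, since dead cells are
cumulative) and dx = x - x0. When x is within a small tolerance of x0 the
expression is degenerate and a short Taylor expansion of log2(x/x0)
around x = x0 is used instead.

The rates are normalized against the untreated control and mapped onto
bounded scores: the cytostatic component GR_S = 2^(ks(c)/ks(0)) - 1,
clipped to [0, 1] (1 = uninhibited division, 0 = full arrest), and the
cytotoxic component GR_T = 2^(kd(0) - kd(c)) - 1, clipped to [-1, 0]
(0 = no drug-induced death, -1 = maximal killing). Each component gets
its own Hill fit, yielding GEC_S_50, GEC_T_50, GR_T_max and GR_T_50.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gr_metrics import _fit_sigmoid_bounded

__all__ = [
    "RatePair",
    "StaticToxicValues",
    "StaticToxicCurves",
    "rates_from_counts",
    "gr_static",
    "gr_toxic",
    "decompose_condition",
    "fit_static_toxic_curves",
]

LN2 = math.log(2.0)
TAYLOR_EPS = 1e-3  # |x - x0| <= eps * x0 switches to the series limit
DEAD_CLAMP = 1.0  # dead cells are cumulative; dd is floored at one cell


@dataclass(frozen=True)
class RatePair:
    """Division and death rates (events/day) estimated for one condition."""

    ks: float
    kd: float
    taylor_used: bool = False
    clamp_used: bool = False


def rates_from_counts(
    x0: float,
    d0: float,
    x: float,
    d: float,
    t_days: float,
    eps: float = TAYLOR_EPS,
    clamp: bool = True,
) -> RatePair:
    """Invert the birth-death model for (ks, kd) from endpoint counts.

    ``t_days`` is the treatment duration in days. ``x <= 0`` is floored at
    a 0.5-cell pseudo-count. With ``clamp`` (the default), ``d - d0`` is
    floored at one cell.
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    if t_days <= 0:
        raise ValueError("t must be > 0 days")
    if x <= 0:
        x = 0.5
    dd = d - d0
    clamp_used = False
    if clamp and dd < DEAD_CLAMP:
        dd = DEAD_CLAMP
        clamp_used = True
    dx = x - x0
    if abs(dx) > eps * x0:
        log2fc = math.log2(x / x0)
        ks = (1.0 + dd / dx) * log2fc / t_days
        kd = (dd / dx) * log2fc / t_days
        return RatePair(ks, kd, taylor_used=False, clamp_used=clamp_used)
    # x ~= x0: expand log2(x/x0)/dx = (delta - delta^2/2 + delta^3/3)/(delta
    # x0 ln2), removing the 0/0; the leading term is (dx + dd)/(t x0 ln2)
    delta = dx / x0
    corr = 1.0 - delta / 2.0 + delta * delta / 3.0
    ks = (dx + dd) * corr / (t_days * x0 * LN2)
    kd = dd * corr / (t_days * x0 * LN2)
    return RatePair(ks, kd, taylor_used=True, clamp_used=clamp_used)


def gr_static(ks_c: float, ks_0: float) -> tuple[float, bool]:
    """Cytostatic score GR_S = 2^(ks(c)/ks(0)) - 1, clipped to [0, 1].

    Returns ``(value, clipped)``; rejects non-growing controls.
    """
    if ks_0 <= 0:
        raise ValueError("control division rate must be > 0")
    raw = 2.0 ** (ks_c / ks_0) - 1.0
    clipped = float(np.clip(raw, 0.0, 1.0))
    return clipped, clipped != raw


def gr_toxic(kd_c: float, kd_0: float) -> tuple[float, bool]:
    """Cytotoxic score GR_T = 2^(kd(0) - kd(c)) - 1, clipped to [-1, 0]."""
    raw = 2.0 ** (kd_0 - kd_c) - 1.0
    clipped = float(np.clip(raw, -1.0, 0.0))
    return clipped, clipped != raw


def gr_from_rates(ks_c, kd_c, ks_0, kd_0) -> float:
    """GR value from rates: 2^((ks(c)-kd(c)) / (ks(0)-kd(0))) - 1."""
    return 2.0 ** ((ks_c - kd_c) / (ks_0 - kd_0)) - 1.0


def decompose_condition(
    counts: pd.DataFrame, eps: float = TAYLOR_EPS, clamp: bool = True
) -> pd.DataFrame:
    """Per-dose (ks, kd, GR_S, GR_T) for one cell line x drug condition.

    ``counts`` needs columns ``concentration, x0, d0, x, d, t_days`` and
    must include the untreated control (concentration 0), which anchors
    ks(0) and kd(0). Taylor/clamp/clip flags are propagated per dose.
    """
    required = {"concentration", "x0", "d0", "x", "d", "t_days"}
    missing = required - set(counts.columns)
    if missing:
        raise KeyError(f"missing count columns: {sorted(missing)}")
    ctrl = counts[counts["concentration"] == 0]
    if ctrl.empty:
        raise ValueError("control (concentration 0) counts are required")

    def _rates(rows: pd.DataFrame) -> RatePair:
        pairs = [
            rates_from_counts(r.x0, r.d0, r.x, r.d, r.t_days, eps=eps, clamp=clamp)
            for r in rows.itertuples()
        ]
        return RatePair(
            ks=float(np.median([p.ks for p in pairs])),
            kd=float(np.median([p.kd for p in pairs])),
            taylor_used=any(p.taylor_used for p in pairs),
            clamp_used=any(p.clamp_used for p in pairs),
        )

    r0 = _rates(ctrl)
    rows = []
    for c, grp in counts[counts["concentration"] > 0].groupby("concentration"):
        rc = _rates(grp)
        s, s_clip = gr_static(rc.ks, r0.ks)
        tox, t_clip = gr_toxic(rc.kd, r0.kd)
        flags = []
        if rc.taylor_used:
            flags.append("taylor")
        if rc.clamp_used or r0.clamp_used:
            flags.append("dead_clamp")
        if s_clip:
            flags.append("gr_s_clipped")
        if t_clip:
            flags.append("gr_t_clipped")
        rows.append(
            dict(
                concentration=float(c), ks=rc.ks, kd=rc.kd,
                ks_ctrl=r0.ks, kd_ctrl=r0.kd,
                gr_s=s, gr_t=tox, flags=";".join(flags),
            )
        )
    return pd.DataFrame(rows).sort_values("concentration").reset_index(drop=True)


@dataclass
class StaticToxicCurves:
    """Hill fits of the cytostatic and cytotoxic dose responses."""

    gr_s_inf: float
    gec_s_50: float  # uM; +inf for flat cytostatic response
    h_s: float
    gr_t_inf: float
    gec_t_50: float  # uM; +inf for flat cytotoxic response
    h_t: float
    gr_t_max: float  # mean measured GR_T at the highest dose
    gr_t_50: float  # concentration where fitted GR_T = -0.5, or +inf
    static_flat: bool
    toxic_flat: bool
    flags: list[str] = field(default_factory=list)


def gr_t50_from_fit(gr_t_inf: float, gec_t_50: float, h: float) -> float:
    """Concentration where the rising-Hill toxic curve reaches -0.5."""
    if gr_t_inf >= -0.5 or not np.isfinite(gec_t_50):
        return float("inf")
    ratio = 0.5 / (-gr_t_inf - 0.5)
    return gec_t_50 * ratio ** (1.0 / h)


def fit_static_toxic_curves(doses, gr_s, gr_t) -> StaticToxicCurves:
    """Fit per-component sigmoids and derive the decomposition metrics.

    The cytostatic curve is the falling sigmoid GR_S(c) = inf +
    (1 - inf)/(1 + (c/GEC_S_50)^h) with inf in [0, 1]; the cytotoxic
    curve is the rising Hill GR_T(c) = inf * (c/GEC_T_50)^h /
    (1 + (c/GEC_T_50)^h) with inf in [-1, 0].
    """
    doses = np.asarray(doses, dtype=float)
    gr_s = np.asarray(gr_s, dtype=float)
    gr_t = np.asarray(gr_t, dtype=float)
    if len(np.unique(doses)) < 5:
        raise ValueError("need >= 5 distinct doses")

    flags: list[str] = []
    ps, _, s_flat, s_bound = _fit_sigmoid_bounded(doses, gr_s, (0.0, 1.0))
    pt, _, t_flat, t_bound = _fit_sigmoid_bounded(doses, gr_t, (-1.0, 0.0), rising=True)
    top = doses.max()
    gr_t_max = float(np.mean(gr_t[doses == top]))

    if s_flat:
        s_inf, gec_s, h_s = float(np.mean(gr_s)), float("inf"), float("nan")
        flags.append("static_flat")
    else:
        s_inf, gec_s, h_s = float(ps[0]), float(10.0 ** ps[1]), float(ps[2])
        if s_bound:
            flags.append("gec_s_50_at_bound")
    if t_flat:
        t_inf, gec_t, h_t = float(np.mean(gr_t)), float("inf"), float("nan")
        gr_t_50 = float("inf")
        flags.append("toxic_flat")
    else:
        t_inf, gec_t, h_t = float(pt[0]), float(10.0 ** pt[1]), float(pt[2])
        gr_t_50 = gr_t50_from_fit(t_inf, gec_t, h_t)
        if t_bound:
            flags.append("gec_t_50_at_bound")
    return StaticToxicCurves(
        gr_s_inf=s_inf, gec_s_50=gec_s, h_s=h_s,
        gr_t_inf=t_inf, gec_t_50=gec_t, h_t=h_t,
        gr_t_max=gr_t_max, gr_t_50=gr_t_50,
        static_flat=s_flat, toxic_flat=t_flat, flags=flags,
    )
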