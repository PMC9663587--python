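# Methods

## Population model and rate estimation

The live population `x` and cumulative dead population `d` follow an
exponential birth-death model with constant per-day rates over the
assay: `dx/dt = ln(2)(k_s - k_d)x`, `dd/dt = ln(2) k_d x`. The `ln(2)`
factor makes `k_s` a doubling rate (divisions/day) rather than a
continuous growth rate, so control growth is directly comparable to the
doublings/day reported for cell-line panels. The closed-form solution is

    x(t) = x0 · 2^((k_s - k_d) t)
    d(t) = d0 + k_d/(k_s - k_d) · (x - x0)        (k_s ≠ k_d)
    d(t) = d0 + ln(2) · k_d · x0 · t              (k_s = k_d)

and the model is inverted exactly for `(k_s, k_d)` from two time points.
Assumptions worth stating: rates are constant over the assay (a single
on-treatment time point cannot resolve time dependence), dead cells are
cumulative and do not lyse, and the time-zero plate is representative of
every treated well at drug addition.

Numerical choices:

- **Dead-cell clamp.** `Δd = d - d0` is floored at 1 cell, because a
  negative increment can only be noise when death is cumulative. The
  clamp makes the inversion inexact at `k_d ≈ 0` by O(1/x0); flags
  (`dead_clamp`) keep this inspectable, and it can be disabled for
  analytic work on noise-free counts.
- **Taylor branch.** When `|Δx| ≤ ε·x0` (ε = 1e-3) the `Δd/Δx` form is
  a 0/0; we switch to the series `log2(x/x0)/Δx ≈ (1 - δ/2 + δ²/3)/(x0
  ln 2)` with `δ = Δx/x0`. Three terms keep the two branches within
  ~1e-10 of each other at the switch, so the estimate is continuous to
  well below the 1e-4 level that matters downstream.
- **Total-kill wells.** `x = 0` is floored at 0.5 cells (flagged), so a
  complete kill maps to a large negative GR instead of NaN.

## GR metrics and component scores

`GR(c) = 2^(log2(x/x0)/log2(x_ctrl/x0)) - 1` uses per-cell-line medians:
`x0`, `d0` over time-zero wells, `x_ctrl` over same-plate negative
controls (medians resist single bad wells). The dose-response sigmoid
`GR(c) = GR_inf + (1-GR_inf)/(1+(c/GEC50)^h)` is fitted by bounded least
squares (`GR_inf ∈ [-1,1]`, `h ∈ [0.1,5]`, `GEC50` within ±2 decades of
the tested range) from three fixed starts; a sigmoid-vs-constant F-test
at α = 0.05 decides flat fits, which report `GEC50 = GR50 = +∞` and
`GR_AOC` from the constant. `GRmax` is the mean measured GR at the top
dose, not the fitted asymptote, since the asymptote extrapolates beyond
the tested range. `GR_AOC` is the trapezoidal integral of `1 - GR` over
log10 dose divided by the range width (0 = inert, 1 = stasis across the
range, 2 = complete kill).

The cytostatic score is `GR_S = 2^(k_s(c)/k_s(0)) - 1` clipped to [0,1];
the cytotoxic score `GR_T = 2^(k_d(0)-k_d(c)) - 1` clipped to [-1,0]
(clips flagged, raw values recoverable from the rates). `gr_T` uses
per-day rate differences, so the magnitude of `GR_T` depends on the time
unit; days is the package-wide convention and constructors accept hours.
When the control is death-free and divides once per day,
`(GR_S+1)(GR_T+1) = GR+1` exactly; otherwise it is an approximation.
The toxic curve is fitted with a rising Hill form
`GR_T(c) = GR_T_inf · (c/GEC_T_50)^h / (1+(c/GEC_T_50)^h)` — the
component metrics constrain only the midpoint and plateau, and this is
the minimal monotone form with the right limits. `GR_T_50` (where the
fitted curve reaches -0.5) has the closed form
`GEC_T_50 · (0.5/(|GR_T_inf|-0.5))^(1/h)` when the plateau passes -0.5.

QC flags and their defaults (all configurable): fewer than 3 negative
controls; fitted `GEC50` outside the tested range or GR at top dose
still above 0.5; fit RMSE above 0.15; optimizer stopped at a bound.

## Gating

Per channel, the ring (perinuclear background) intensity is subtracted
from the nuclear mean, floored at 1 a.u. so log10 is defined, and the
cutoff placed at the global minimum of a Gaussian KDE (Silverman
bandwidth, 1024-point grid) between the two most prominent peaks
(prominence ≥ 1% of the density maximum). Unimodal wells — no positive
population — fall back to `mode + 2·1.4826·MAD` and are flagged, so
everything classifies negative rather than failing. Thresholds are fitted
on cells pooled per plate per cell line by default: wells with strong
killing have too few cells for a stable KDE.

DNA content is mean nuclear Hoechst × nuclear area (no ring subtraction;
the integrated signal is the ploidy proxy). The G1 mode is the highest
DNA-density peak; the G2 mode is the detected peak nearest G1 + log10(2)
(accepted within ±0.2 log10 units), imputed at exactly twice G1 when
absent. Window half-width `w = 0.15` log10 units; the G1/G2 boundary is
the density minimum between the modes. Classification precedence:
corpse > dead > M (pH3) > S (EdU) > DNA windows — pH3 wins over EdU
because mitotic cells are 4N and EdU label can persist into M.

## Synthetic screens

The simulator emulates the study conditions end to end: nine-point
half-log dose series (1e-4 to ~3 uM), triplicate wells, 72-h assays,
time-zero reference counts, control growth of ~1 division/day, and
multiplicative lognormal count noise at 5% CV (the well-to-well
variability typical of replicate screens; the noise is mean-preserving).
Channel intensities are two-component log10-normal mixtures with ≥4-sd
separation by default (negative/positive means 1.0/2.6 for LDR, 1.2/3.0
for EdU, 1.0/2.8 for pH3, sd 0.12); DNA content is bimodal with the G2
mode at exactly twice G1 (sd 0.05 log10), S-phase DNA uniform between
the modes, and corpses below 1% of the G1 mode. Spatial layouts are
uniform or parent-offspring clustered (10 Gaussian clusters, sd 2% of
the well width, emulating clonal colonies).

What the simulator does **not** capture: segmentation errors and doublet
nuclei, spatial illumination gradients, channel crosstalk, overlapping
intensity populations, dead-cell lysis, and time-varying rates. Passing
tests therefore demonstrate correctness of the computations under the
stated model, not robustness to every imaging artifact; the gating
accuracy bounds in the tests hold for well-separated mixtures by
construction.

Problem sizes used by the test suite and the acceptance script — 1000
random rate pairs for the inversion property, 200 simulated dose-response
curves for fit recovery, 2000-cell wells for gating, 100 seeded wells
for the spatial bands — are large enough that the pass/fail frequencies
are stable across seeds while the whole suite stays quick to run.

## Spatial statistics

Within a well, each S-phase cell's Euclidean distance to its nearest
S-phase neighbor (d_SS) and to the nearest cell of any other phase
(d_SO) are computed with a k-d tree (verified exactly against an O(n²)
oracle). The two distributions are compared with a two-sided rank-sum
test plus the ratio of medians; clustered S cells drive the ratio well
below 1. The rank-sum test is a convention choice — the medians are
reported so any other comparison can be substituted. Fields are pooled
per well assuming well-global coordinates; with only field-local
coordinates the analysis runs per field and is flagged.

## Estimators documented as approximations

S-phase duration is estimated as `f_S × T_division`. A short EdU pulse
in an exponentially growing, age-structured culture slightly
underestimates the true S fraction of the cycle; a first-order estimate
is reported deliberately, since resolving the age structure needs
assumptions the data cannot check.

## Known limitations

- Two time points cannot detect adaptation or delayed killing; rates
  are averages over the assay window.
- Dead-cell lysis deflates `k_d`; nothing in endpoint data can correct
  this, so low total count combined with low dead count deserves a
  hard look at the raw wells.
- The fitted `GEC_S_50` of the Hill-fitted `GR_S` curve differs from the
  midpoint of the underlying `k_s(c)` Hill by up to ~30%, because
  `2^(k_s/k_s0) - 1` warps the Hill shape; the bias is well inside the
  2-fold reproducibility of midpoint estimates under realistic noise.
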