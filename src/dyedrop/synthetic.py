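"""Generative model of a dye-drop-style viability/cell-cycle screen.

The simulator produces both well-level live/dead counts and single-cell
feature tables with known ground truth, so that gating, GR metrics, the
cytostatic/cytotoxic decomposition and the spatial statistics can all be
validated without real microscopy data.

Population kinetics follow an exponential birth-death model: live cells
``x`` divide at a doubling rate ``ks`` (divisions/day) and die at a rate
``kd`` (deaths/day), with dead cells ``d`` accumulating::

    dx/dt = ln(2) * (ks - kd) * x
    dd/dt = ln(2) * kd * x

Drug dependence of the rates is Hill-shaped: ``ks`` falls from ``ks0``
toward ``ks_inf`` and ``kd`` rises from ``kd0`` toward ``kd_max`` with
concentration. Channel intensities (LDR, EdU, pH3) are two-component
lognormal mixtures (negative vs positive population); DNA content is
bimodal with the G2 mode at exactly twice the G1 mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "KineticGroundTruth",
    "ChannelMixture",
    "IntensityModel",
    "SimulatedWell",
    "rates_at_dose",
    "closed_form_counts",
    "simulate_condition",
    "simulate_cell_table",
]

LN2 = math.log(2.0)

#: canonical single-cell feature columns emitted by the simulator and
#: consumed by the gating module
CELL_COLUMNS = [
    "well",
    "field",
    "x",
    "y",
    "nuclear_area",
    "hoechst_nuclear",
    "hoechst_ring",
    "ldr_nuclear",
    "ldr_ring",
    "edu_nuclear",
    "edu_ring",
    "ph3_nuclear",
    "ph3_ring",
    "true_class",
]


@dataclass(frozen=True)
class KineticGroundTruth:
    """Hill-parameterized dose dependence of division and death rates.

    Rates are in events/day; concentrations in the same unit as the doses
    passed to :func:`rates_at_dose` (canonically uM).
    """

    ks0: float = 1.0  # divisions/day at c = 0
    kd0: float = 0.0  # deaths/day at c = 0
    ks_inf: float = 0.0  # division rate at saturating dose
    ks_ec50: float = 0.1  # midpoint of the cytostatic effect (conc.)
    ks_hill: float = 2.0
    kd_max: float = 0.0  # death rate at saturating dose
    kd_ec50: float = 1.0  # midpoint of the cytotoxic effect (conc.)
    kd_hill: float = 2.0

    def __post_init__(self) -> None:
        if self.ks0 <= 0:
            raise ValueError("ks0 must be > 0")
        if self.kd0 < 0:
            raise ValueError("kd0 must be >= 0")
        if self.ks_inf < 0 or self.kd_max < 0:
            raise ValueError("saturating rates must be >= 0")
        if self.ks_ec50 <= 0 or self.kd_ec50 <= 0:
            raise ValueError("Hill midpoints must be > 0")
        if self.ks_hill <= 0 or self.kd_hill <= 0:
            raise ValueError("Hill slopes must be > 0")


def rates_at_dose(gt: KineticGroundTruth, c: float) -> tuple[float, float]:
    """Evaluate (ks, kd) in events/day at concentration ``c``.

    ``ks`` decreases from ``ks0`` toward ``ks_inf`` and ``kd`` increases
    from ``kd0`` toward ``kd_max``, each along a Hill curve.
    """
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c == 0:
        return gt.ks0, gt.kd0
    fs = 1.0 / (1.0 + (c / gt.ks_ec50) ** gt.ks_hill)
    ft = 1.0 - 1.0 / (1.0 + (c / gt.kd_ec50) ** gt.kd_hill)
    ks = gt.ks_inf + (gt.ks0 - gt.ks_inf) * fs
    kd = gt.kd0 + (gt.kd_max - gt.kd0) * ft
    return ks, kd


def closed_form_counts(
    ks: float, kd: float, x0: float, d0: float = 0.0, t: float = 1.0
) -> tuple[float, float]:
    """Exact solution of the birth-death ODE with constant rates.

    Parameters
    ----------
    ks, kd : float
        Division and death rates in events/day.
    x0, d0 : float
        Live and dead counts at treatment start.
    t : float
        Duration in days.

    Returns
    -------
    (x, d) : live and cumulative dead counts at time ``t``.
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    x = x0 * 2.0 ** ((ks - kd) * t)
    if ks == kd:
        d = d0 + LN2 * kd * x0 * t
    else:
        d = d0 + kd / (ks - kd) * (x - x0)
    return x, d


@dataclass(frozen=True)
class ChannelMixture:
    """Two-component log10-domain intensity mixture for one stain channel."""

    neg_mean: float  # log10 a.u.
    neg_sd: float
    pos_mean: float
    pos_sd: float

    def __post_init__(self) -> None:
        if self.pos_mean <= self.neg_mean:
            raise ValueError("positive mean must exceed negative mean")
        if self.neg_sd < 0 or self.pos_sd < 0:
            raise ValueError("sds must be >= 0")

    def draw(self, rng: np.random.Generator, n: int, positive: bool) -> np.ndarray:
        mu, sd = (self.pos_mean, self.pos_sd) if positive else (self.neg_mean, self.neg_sd)
        return 10.0 ** rng.normal(mu, sd, size=n)


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel intensity mixtures and the DNA-content model.

    ``dna_g1_mode`` is the G1 DNA content in arbitrary units; the G2 mode
    is fixed at exactly twice the G1 mode (4N vs 2N). Corpses carry DNA
    below ``corpse_floor_frac * dna_g1_mode``.
    """

    ldr: ChannelMixture = field(
        default_factory=lambda: ChannelMixture(1.0, 0.12, 2.6, 0.12)
    )
    edu: ChannelMixture = field(
        default_factory=lambda: ChannelMixture(1.2, 0.12, 3.0, 0.12)
    )
    ph3: ChannelMixture = field(
        default_factory=lambda: ChannelMixture(1.0, 0.12, 2.8, 0.12)
    )
    dna_g1_mode: float = 1000.0  # a.u.
    dna_sd: float = 0.05  # log10 units
    corpse_floor_frac: float = 0.01
    nuclear_area: float = 100.0  # area units; DNA = mean intensity * area
    ring_background: float = 50.0  # additive a.u. on every nuclear mean
    well_width: float = 1000.0  # square well side, coordinate units

    @property
    def dna_g2_mode(self) -> float:
        return 2.0 * self.dna_g1_mode

    @property
    def corpse_floor(self) -> float:
        return self.corpse_floor_frac * self.dna_g1_mode


@dataclass
class SimulatedWell:
    """One simulated well: the cell table plus its ground-truth tallies."""

    well: str
    cells: pd.DataFrame
    true_counts: dict[str, int]
    seed: int


def simulate_condition(
    gt: KineticGroundTruth,
    doses: np.ndarray | list[float],
    x0: float,
    d0: float = 0.0,
    t: float = 3.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate live/dead counts across a dose series.

    Counts from :func:`closed_form_counts` are perturbed by mean-preserving
    multiplicative lognormal noise with coefficient of variation
    ``noise_cv``; ``noise_cv=0`` returns the exact closed form.

    Returns a tidy frame with columns ``concentration, x0, d0, x, d, t_days,
    ks_true, kd_true``.
    """
    doses = np.asarray(doses, dtype=float)
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2))
    rows = []
    for c in doses:
        ks, kd = rates_at_dose(gt, float(c))
        x, d = closed_form_counts(ks, kd, x0, d0, t)
        if noise_cv > 0:
            x *= rng.lognormal(-0.5 * sigma**2, sigma)
            d = d0 + (d - d0) * rng.lognormal(-0.5 * sigma**2, sigma)
        rows.append(
            dict(
                concentration=float(c), x0=x0, d0=d0, x=x, d=d,
                t_days=t, ks_true=ks, kd_true=kd,
            )
        )
    return pd.DataFrame(rows)


def _place_uniform(rng: np.random.Generator, n: int, width: float) -> np.ndarray:
    return rng.uniform(0.0, width, size=(n, 2))


def _place_clustered(
    rng: np.random.Generator, n: int, width: float, n_clusters: int, sd: float
) -> np.ndarray:
    """Parent-offspring (Neyman-Scott-style) clustered point pattern."""
    parents = rng.uniform(0.0, width, size=(n_clusters, 2))
    assign = rng.integers(0, n_clusters, size=n)
    pts = parents[assign] + rng.normal(0.0, sd, size=(n, 2))
    return np.clip(pts, 0.0, width)


def simulate_cell_table(
    counts: dict[str, int],
    im: IntensityModel | None = None,
    spatial_mode: str = "uniform",
    n_clusters: int = 10,
    cluster_sd: float | None = None,
    well: str = "A1",
    seed: int | None = None,
) -> SimulatedWell:
    """Emit one CellRecord row per simulated cell with known class labels.

    ``counts`` maps class names (``G1, S, G2, M, subG1, dead, corpse``) to
    cell numbers. Dead cells draw from the positive LDR component; S cells
    from the positive EdU component with DNA uniform between the G1 and G2
    modes; M cells from the positive pH3 component at the G2 mode; corpses
    have DNA below the corpse floor and positive LDR. ``spatial_mode``
    places S cells either uniformly or via a parent-offspring cluster
    process (all other cells are uniform).
    """
    if im is None:
        im = IntensityModel()
    if spatial_mode not in ("uniform", "clustered"):
        raise ValueError(f"unknown spatial_mode {spatial_mode!r}")
    known = {"G1", "S", "G2", "M", "subG1", "dead", "corpse"}
    unknown = set(counts) - known
    if unknown:
        raise ValueError(f"unknown cell classes: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")

    rng = np.random.default_rng(seed)
    if cluster_sd is None:
        cluster_sd = 0.02 * im.well_width

    blocks: list[pd.DataFrame] = []
    for cls in ["G1", "S", "G2", "M", "subG1", "dead", "corpse"]:
        n = int(counts.get(cls, 0))
        if n == 0:
            continue
        # DNA content per class, in a.u.
        if cls == "G1":
            dna = im.dna_g1_mode * 10.0 ** rng.normal(0.0, im.dna_sd, n)
        elif cls == "G2" or cls == "M":
            dna = im.dna_g2_mode * 10.0 ** rng.normal(0.0, im.dna_sd, n)
        elif cls == "S":
            dna = rng.uniform(im.dna_g1_mode, im.dna_g2_mode, n)
        elif cls == "subG1":
            dna = 0.5 * im.dna_g1_mode * 10.0 ** rng.normal(0.0, im.dna_sd, n)
        elif cls == "dead":
            dna = im.dna_g1_mode * 10.0 ** rng.normal(0.0, im.dna_sd, n)
        else:  # corpse: essentially no Hoechst signal
            dna = rng.uniform(0.0, im.corpse_floor, n)
        ldr = im.ldr.draw(rng, n, positive=cls in ("dead", "corpse"))
        edu = im.edu.draw(rng, n, positive=cls == "S")
        ph3 = im.ph3.draw(rng, n, positive=cls == "M")
        if cls == "S" and spatial_mode == "clustered":
            xy = _place_clustered(rng, n, im.well_width, n_clusters, cluster_sd)
        else:
            xy = _place_uniform(rng, n, im.well_width)
        b = im.ring_background
        blocks.append(
            pd.DataFrame(
                {
                    "well": well,
                    "field": 1,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                    "nuclear_area": im.nuclear_area,
                    "hoechst_nuclear": dna / im.nuclear_area,
                    "hoechst_ring": b,
                    "ldr_nuclear": ldr + b,
                    "ldr_ring": b,
                    "edu_nuclear": edu + b,
                    "edu_ring": b,
                    "ph3_nuclear": ph3 + b,
                    "ph3_ring": b,
                    "true_class": cls,
                }
            )
        )
    if blocks:
        cells = pd.concat(blocks, ignore_index=True)
        # shuffle so class blocks are not positionally ordered
        cells = cells.sample(frac=1.0, random_state=rng.integers(2**31)).reset_index(
            drop=True
        )
    else:
        cells = pd.DataFrame(columns=CELL_COLUMNS)
    true_counts = {k: int(counts.get(k, 0)) for k in sorted(known)}
    return SimulatedWell(well=well, cells=cells, true_counts=true_counts, seed=seed or 0)


def write_ground_truth(path, gt: KineticGroundTruth) -> None:
    """Serialize kinetic ground truth as a key=value sidecar text file."""
    with open(path, "w") as fh:
        for k, v in vars(gt).items():
            fh.write(f"{k}={v!r}\n")
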