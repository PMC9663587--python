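"""Tabular I/O: segmentation feature tables, plate maps, joins.

Segmentation software exports differ only in column headers (Columbus vs
MetaXpress dialects), so feature tables are read through a ``ColumnMap``
that renames source headers onto the canonical schema used throughout the
package. Plate maps assign each well a cell line, drug, concentration and
role; treatment wells are joined with time-zero and negative-control
summaries into per-condition count records for the GR calculations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ColumnMap",
    "read_feature_table",
    "read_platemap",
    "join_conditions",
    "normalize_well",
]

CANONICAL_FIELDS = [
    "well", "field", "x", "y", "nuclear_area",
    "hoechst_nuclear", "hoechst_ring",
    "ldr_nuclear", "ldr_ring",
    "edu_nuclear", "edu_ring",
    "ph3_nuclear", "ph3_ring",
]

ROLES = {"treatment", "negative_control", "time_zero", "empty"}

_UNIT_TO_UM = {"um": 1.0, "µm": 1.0, "nm": 1e-3, "mm": 1e3, "m": 1e6, "pm": 1e-6}

_WELL_RE = re.compile(r"^([A-Pa-p])0*([1-9]\d?)$")


def normalize_well(well: str, n_rows: int = 16, n_cols: int = 24) -> str:
    """Canonical well address: upper-case row letter + unpadded column."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"unparseable well address {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if ord(row) - ord("A") >= n_rows or col > n_cols:
        raise ValueError(f"well {well!r} outside a {n_rows}x{n_cols} plate")
    return f"{row}{col}"


@dataclass
class ColumnMap:
    """Maps canonical field names to the source file's column headers."""

    mapping: dict[str, str]
    coordinate_unit: str = "pixel"
    intensity_note: str = "a.u."

    def __post_init__(self) -> None:
        missing = [f for f in CANONICAL_FIELDS if f not in self.mapping]
        if missing:
            raise ValueError(f"ColumnMap missing canonical fields: {missing}")
        sources = list(self.mapping.values())
        dupes = {s for s in sources if sources.count(s) > 1}
        if dupes:
            raise ValueError(f"source columns mapped twice: {sorted(dupes)}")

    @classmethod
    def identity(cls) -> "ColumnMap":
        return cls({f: f for f in CANONICAL_FIELDS})

    @classmethod
    def from_config(cls, path) -> "ColumnMap":
        """Read a key=value text config; non-field keys set metadata."""
        mapping, meta = {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                k, v = k.strip(), v.strip()
                if k in ("coordinate_unit", "intensity_note"):
                    meta[k] = v
                else:
                    mapping[k] = v
        return cls(mapping, **meta)


def read_feature_table(path, cmap: ColumnMap | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a segmentation feature table onto the canonical schema.

    Delimiter is sniffed from the extension unless given. Rows whose
    numeric fields fail to parse are dropped and reported (by input line
    number) in the frame's ``attrs['bad_rows']``.
    """
    if cmap is None:
        cmap = ColumnMap.identity()
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [src for src in cmap.mapping.values() if src not in raw.columns]
    if missing:
        canon = [k for k, v in cmap.mapping.items() if v in missing]
        raise KeyError(f"missing mapped columns {missing} (canonical: {canon})")
    table = raw[[cmap.mapping[f] for f in CANONICAL_FIELDS]].copy()
    table.columns = CANONICAL_FIELDS

    numeric = [f for f in CANONICAL_FIELDS if f not in ("well",)]
    for col in numeric:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    bad = table[numeric].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        table.attrs["bad_rows"] = [int(i) + 2 for i in table.index[bad]]
        table = table[~bad].reset_index(drop=True)
    else:
        table.attrs["bad_rows"] = []
    table["well"] = table["well"].map(normalize_well)
    table.attrs["coordinate_unit"] = cmap.coordinate_unit
    return table


@dataclass
class PlateMap:
    """Validated plate design: one row per well."""

    table: pd.DataFrame  # well, cell_line, drug, concentration (uM), role
    n_rows: int = 16
    n_cols: int = 24
    flags: list[str] = field(default_factory=list)

    def wells(self, role: str) -> pd.DataFrame:
        return self.table[self.table["role"] == role]


def read_platemap(path, concentration_unit: str = "uM") -> PlateMap:
    """Read a long-format plate map CSV and normalize it.

    Columns: ``well, cell_line, drug, concentration, role``; an optional
    ``concentration_unit`` column (or the argument) converts doses to uM.
    Duplicate wells, unknown roles and non-positive treatment doses are
    rejected; a plate without negative controls is flagged.
    """
    pm = pd.read_csv(path)
    required = {"well", "cell_line", "drug", "concentration", "role"}
    missing = required - set(pm.columns)
    if missing:
        raise KeyError(f"plate map missing columns: {sorted(missing)}")
    pm["well"] = pm["well"].map(normalize_well)
    if pm["well"].duplicated().any():
        dupes = pm.loc[pm["well"].duplicated(), "well"].tolist()
        raise ValueError(f"duplicate wells in plate map: {dupes}")
    bad_roles = set(pm["role"]) - ROLES
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    if "concentration_unit" in pm.columns:
        factors = pm["concentration_unit"].str.lower().map(_UNIT_TO_UM)
        if factors.isna().any():
            raise ValueError("unknown concentration unit in plate map")
        pm["concentration"] = pm["concentration"].astype(float) * factors
        pm = pm.drop(columns=["concentration_unit"])
    else:
        unit = concentration_unit.lower()
        if unit not in _UNIT_TO_UM:
            raise ValueError(f"unknown concentration unit {concentration_unit!r}")
        pm["concentration"] = pm["concentration"].astype(float) * _UNIT_TO_UM[unit]
    treat = pm["role"] == "treatment"
    if (pm.loc[treat, "concentration"] <= 0).any():
        raise ValueError("treatment wells must have concentration > 0")
    flags = []
    if not (pm["role"] == "negative_control").any():
        flags.append("no_negative_controls")
    return PlateMap(table=pm.reset_index(drop=True), flags=flags)


def read_platemap_grid(path_prefix, cell_line: str) -> PlateMap:
    """Read 16x24 grid sheets (``<prefix>_drug.csv``, ``_concentration.csv``,
    ``_role.csv``) into the same long-format PlateMap."""
    import pathlib

    prefix = pathlib.Path(str(path_prefix))
    sheets = {}
    for part in ("drug", "concentration", "role"):
        p = prefix.parent / f"{prefix.name}_{part}.csv"
        sheets[part] = pd.read_csv(p, index_col=0)
    rows = []
    for r in sheets["role"].index:
        for c in sheets["role"].columns:
            role = sheets["role"].loc[r, c]
            if pd.isna(role):
                continue
            rows.append(
                dict(
                    well=normalize_well(f"{r}{c}"),
                    cell_line=cell_line,
                    drug=sheets["drug"].loc[r, c],
                    concentration=float(sheets["concentration"].loc[r, c]),
                    role=role,
                )
            )
    import io as _io

    buf = _io.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    buf.seek(0)
    return read_platemap(buf)


def join_conditions(
    summaries: pd.DataFrame,
    pm: PlateMap,
    t0_summaries: pd.DataFrame,
    t_hours: float = 72.0,
) -> pd.DataFrame:
    """Join per-well summaries with the plate design into condition counts.

    ``summaries`` and ``t0_summaries`` need columns ``well, live, dead``.
    Per cell line, x0/d0 are the medians across its time-zero wells and
    x_ctrl the median of same-plate negative-control wells at time t.
    Cell lines without time-zero data are excluded (flagged in
    ``attrs['excluded']``). One output row per treatment well.
    """
    des = pm.table
    sm = summaries.merge(des, on="well", how="inner", validate="one_to_one")
    t0 = t0_summaries.merge(des, on="well", how="inner")

    t0_by_line = t0[t0["role"] == "time_zero"].groupby("cell_line")[["live", "dead"]].median()
    ctrl_by_line = (
        sm[sm["role"] == "negative_control"].groupby("cell_line")["live"].median()
    )
    n_ctrl_by_line = sm[sm["role"] == "negative_control"].groupby("cell_line").size()

    rows, excluded = [], []
    for rec in sm[sm["role"] == "treatment"].itertuples():
        if rec.cell_line not in t0_by_line.index:
            excluded.append(rec.well)
            continue
        if rec.cell_line not in ctrl_by_line.index:
            excluded.append(rec.well)
            continue
        rows.append(
            dict(
                cell_line=rec.cell_line,
                drug=rec.drug,
                concentration=rec.concentration,
                well=rec.well,
                x0=float(t0_by_line.loc[rec.cell_line, "live"]),
                d0=float(t0_by_line.loc[rec.cell_line, "dead"]),
                x_ctrl=float(ctrl_by_line.loc[rec.cell_line]),
                n_controls=int(n_ctrl_by_line.loc[rec.cell_line]),
                x=float(rec.live),
                d=float(rec.dead),
                t_days=t_hours / 24.0,
            )
        )
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = excluded
    return out


def write_table(df: pd.DataFrame, path) -> None:
    """Write a canonical output table with 6-significant-digit floats."""
    df.to_csv(path, index=False, float_format="%.6g")
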