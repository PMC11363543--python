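"""Panel data model, CSV interchange and packaged reference tables.

The analysis operates on a balanced province × year panel: five DEA inputs
(facilities, beds, physicians, nurses, pharmacists), four DEA outputs
(visits, inpatients, discharges, bed-utilization rate) and up to thirteen
socio-economic covariates per decision-making unit (DMU) and year.  The
canonical interchange is a long-format CSV with one row per (unit, year);
wide format is supported read-only for score tables.

Packaged fixtures hold the published reference tables — the 29 × 10
efficiency score panel, the per-province Malmquist decomposition, the
per-year global Moran statistics — plus the first-order rook contiguity
edge list over the 29 provinces (with Hainan linked to Guangdong so no
unit is isolated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "FixtureTable",
    "PanelSchema",
    "load_panel",
    "write_panel",
    "load_fixture",
    "load_adjacency",
    "aggregate_table",
    "FIXTURE_NAMES",
    "PROVINCES_29",
]

FIXTURE_NAMES = (
    "table1_efficiency",
    "table3_malmquist",
    "table4_moran",
    "adjacency_rook29",
)

#: The 29 study provinces in published DMU order (Beijing, Shanghai, Hong
#: Kong, Macao and Taiwan are outside the study set).
PROVINCES_29 = (
    "Tianjin", "Hebei", "Shanxi", "Inner Mongolia", "Liaoning", "Jilin",
    "Heilongjiang", "Jiangsu", "Zhejiang", "Anhui", "Fujian", "Jiangxi",
    "Shandong", "Henan", "Hubei", "Hunan", "Guangdong", "Guangxi",
    "Hainan", "Chongqing", "Sichuan", "Guizhou", "Yunnan", "Xizang",
    "Shaanxi", "Gansu", "Qinghai", "Ningxia", "Xinjiang",
)


@dataclass(frozen=True)
class PanelSchema:
    """Maps long-CSV column names onto panel roles.

    Parameters
    ----------
    unit, year
        Key columns identifying the DMU and the period.
    inputs, outputs
        Ordered column names of the DEA input and output variables.
    covariates
        Ordered column names of regression covariates (may be empty).
    """

    inputs: tuple[str, ...]
    outputs: tuple[str, ...]
    covariates: tuple[str, ...] = ()
    unit: str = "unit"
    year: str = "year"


@dataclass
class PanelDataset:
    """Balanced units × periods panel of DEA data and covariates.

    Arrays are indexed ``[unit, variable, period]``; orderings are fixed and
    shared.  Inputs and outputs must be strictly positive because the
    slacks-based efficiency measure divides by each evaluated input and
    output level.
    """

    unit_ids: list[str]
    period_ids: list[int]
    inputs: np.ndarray  # (n, m, T)
    outputs: np.ndarray  # (n, s, T)
    covariates: np.ndarray | None = None  # (n, p, T)
    input_names: list[str] = field(default_factory=list)
    output_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.outputs = np.asarray(self.outputs, dtype=float)
        n, T = len(self.unit_ids), len(self.period_ids)
        if self.inputs.shape[0] != n or self.inputs.shape[2] != T:
            raise ValueError(f"inputs shape {self.inputs.shape} mismatches n={n}, T={T}")
        if self.outputs.shape[0] != n or self.outputs.shape[2] != T:
            raise ValueError(f"outputs shape {self.outputs.shape} mismatches n={n}, T={T}")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.shape[0] != n or self.covariates.shape[2] != T:
                raise ValueError("covariate array mismatches panel dimensions")
            if not np.isfinite(self.covariates).all():
                raise ValueError("covariates contain missing or non-finite cells")
        for name, arr in (("inputs", self.inputs), ("outputs", self.outputs)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contain missing or non-finite cells")
            if (arr <= 0).any():
                u, v, t = np.argwhere(arr <= 0)[0]
                raise ValueError(
                    f"nonpositive {name[:-1]} value for unit "
                    f"{self.unit_ids[u]!r}, year {self.period_ids[t]}, "
                    f"variable index {v}: SBM efficiency is undefined"
                )
        if not self.input_names:
            self.input_names = [f"x{i + 1}" for i in range(self.n_inputs)]
        if not self.output_names:
            self.output_names = [f"y{k + 1}" for k in range(self.n_outputs)]
        if self.covariates is not None and not self.covariate_names:
            self.covariate_names = [f"X{j + 1}" for j in range(self.covariates.shape[1])]

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_periods(self) -> int:
        return len(self.period_ids)

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.outputs.shape[1]


@dataclass(frozen=True)
class FixtureTable:
    """A packaged published table with its name and labelled values."""

    name: str
    values: pd.DataFrame


def _data_path(filename: str):
    return resources.files("thcdea.data").joinpath(filename)


def load_fixture(name: str) -> FixtureTable:
    """Load one of the packaged reference tables.

    ``table1_efficiency`` — 29 provinces × 10 years of super-SBM scores;
    ``table3_malmquist`` — 29 provinces × (MI, EC, TC);
    ``table4_moran`` — 10 years × (I, Z, p);
    ``adjacency_rook29`` — symmetric rook-contiguity edge list.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    if name == "adjacency_rook29":
        edges = load_adjacency()
        df = pd.DataFrame(edges, columns=["from", "to"])
        return FixtureTable(name=name, values=df)
    with _data_path(f"{name}.csv").open("r") as fh:
        df = pd.read_csv(fh, index_col=0)
    if name == "table1_efficiency":
        df.columns = df.columns.astype(int)
    elif name == "table4_moran":
        df.index = df.index.astype(int)
    return FixtureTable(name=name, values=df)


def load_adjacency(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Read an undirected edge list (one ``a,b`` pair per line, ``#`` comments)."""
    if path is None:
        text = _data_path("adjacency_rook29.txt").read_text()
    else:
        text = Path(path).read_text()
    edges: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = (s.strip() for s in line.split(",", 1))
        if a == b:
            raise ValueError(f"self-loop {a!r} in adjacency list")
        edges.append((a, b))
    return edges


def load_panel(path: str | Path, schema: PanelSchema) -> PanelDataset:
    """Read a long-format CSV into a :class:`PanelDataset`.

    The CSV must contain the schema's key columns plus every named input,
    output and covariate column, with exactly one row per (unit, year).
    Missing cells and nonpositive input/output values are rejected with the
    offending unit/year/field named.
    """
    df = pd.read_csv(path)
    required = [schema.unit, schema.year, *schema.inputs, *schema.outputs, *schema.covariates]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"CSV is missing columns {missing_cols}")

    units = list(dict.fromkeys(df[schema.unit].astype(str)))
    years = sorted(df[schema.year].astype(int).unique())
    key = df.set_index([df[schema.unit].astype(str), df[schema.year].astype(int)])
    if key.index.duplicated().any():
        dup = key.index[key.index.duplicated()][0]
        raise ValueError(f"duplicate cell for unit {dup[0]!r}, year {dup[1]}")

    n, T = len(units), len(years)
    m, s, p = len(schema.inputs), len(schema.outputs), len(schema.covariates)
    inputs = np.empty((n, m, T))
    outputs = np.empty((n, s, T))
    covars = np.empty((n, p, T)) if p else None
    for ui, u in enumerate(units):
        for ti, t in enumerate(years):
            try:
                row = key.loc[(u, t)]
            except KeyError:
                raise ValueError(f"missing cell: unit {u!r}, year {t}") from None
            for vi, col in enumerate(schema.inputs):
                _check_cell(row[col], u, t, col)
                inputs[ui, vi, ti] = row[col]
            for vi, col in enumerate(schema.outputs):
                _check_cell(row[col], u, t, col)
                outputs[ui, vi, ti] = row[col]
            for vi, col in enumerate(schema.covariates):
                if not np.isfinite(row[col]):
                    raise ValueError(f"missing cell: unit {u!r}, year {t}, field {col!r}")
                covars[ui, vi, ti] = row[col]

    return PanelDataset(
        unit_ids=units,
        period_ids=years,
        inputs=inputs,
        outputs=outputs,
        covariates=covars,
        input_names=list(schema.inputs),
        output_names=list(schema.outputs),
        covariate_names=list(schema.covariates),
    )


def _check_cell(value, unit, year, col) -> None:
    if not np.isfinite(value):
        raise ValueError(f"missing cell: unit {unit!r}, year {year}, field {col!r}")
    if value <= 0:
        raise ValueError(
            f"nonpositive value {value} for unit {unit!r}, year {year}, "
            f"field {col!r}: SBM efficiency is undefined"
        )


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write a panel to the canonical long-format CSV (inverse of load_panel)."""
    rows = []
    for ui, u in enumerate(panel.unit_ids):
        for ti, t in enumerate(panel.period_ids):
            row: dict[str, object] = {"unit": u, "year": t}
            for vi, name in enumerate(panel.input_names):
                row[name] = panel.inputs[ui, vi, ti]
            for vi, name in enumerate(panel.output_names):
                row[name] = panel.outputs[ui, vi, ti]
            if panel.covariates is not None:
                for vi, name in enumerate(panel.covariate_names):
                    row[name] = panel.covariates[ui, vi, ti]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def panel_schema(panel: PanelDataset) -> PanelSchema:
    """Schema that round-trips this panel through write_panel/load_panel."""
    return PanelSchema(
        inputs=tuple(panel.input_names),
        outputs=tuple(panel.output_names),
        covariates=tuple(panel.covariate_names) if panel.covariates is not None else (),
    )


def aggregate_table(
    values: pd.DataFrame,
    axis: str = "all",
    method: str = "arithmetic",
) -> pd.Series | float:
    """Mean of a labelled numeric table along rows, columns, or everything.

    ``axis='rows'`` returns one mean per row (the per-province "Mean" column
    of the published score table); ``'columns'`` one mean per column (the
    per-year "Mean" row); ``'all'`` the grand mean over every cell.
    ``method`` is ``'arithmetic'`` or ``'geometric'``; geometric means
    require strictly positive entries.  Results are full precision —
    rounding belongs to display only.
    """
    if axis not in {"rows", "columns", "all"}:
        raise ValueError(f"axis must be rows|columns|all, got {axis!r}")
    if method not in {"arithmetic", "geometric"}:
        raise ValueError(f"method must be arithmetic|geometric, got {method!r}")
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("table contains missing values")
    if method == "geometric":
        if (arr <= 0).any():
            raise ValueError("geometric mean undefined for nonpositive entries")
        log = np.log(arr)
        if axis == "rows":
            return pd.Series(np.exp(log.mean(axis=1)), index=values.index)
        if axis == "columns":
            return pd.Series(np.exp(log.mean(axis=0)), index=values.columns)
        return float(np.exp(log.mean()))
    if axis == "rows":
        return pd.Series(arr.mean(axis=1), index=values.index)
    if axis == "columns":
        return pd.Series(arr.mean(axis=0), index=values.columns)
    return float(arr.mean())
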