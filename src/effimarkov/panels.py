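"""Panel data model for regional efficiency analysis.

Two panel containers are used throughout the package:

* :class:`IndicatorPanel` — raw DEA inputs/outputs per decision-making unit
  (DMU) and year: three inputs (institutions, beds, personnel) and three
  outputs (visits, admissions, family-service frequency).
* :class:`EfficiencyPanel` — one efficiency score ``rho`` per unit-year,
  either computed by the DEA module or loaded from the packaged study panel.

Both are thin wrappers around a validated, canonically sorted
:class:`pandas.DataFrame` (units lexicographic, years ascending). Panels are
balanced: every unit appears in every year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

INPUT_COLS = ["x1", "x2", "x3"]
OUTPUT_COLS = ["y1", "y2", "y3"]

#: Region membership of the 20 in-sample provinces (8 central, 12 western),
#: hard-coded study metadata rather than inferred from data.
REGIONS: dict[str, str] = {
    "Anhui": "central", "Heilongjiang": "central", "Henan": "central",
    "Hubei": "central", "Hunan": "central", "Jiangxi": "central",
    "Jilin": "central", "Shanxi": "central",
    "Chongqing": "western", "Gansu": "western", "Guangxi": "western",
    "Guizhou": "western", "Inner Mongolia": "western", "Ningxia": "western",
    "Qinghai": "western", "Shaanxi": "western", "Sichuan": "western",
    "Tibet": "western", "Xinjiang": "western", "Yunnan": "western",
}


class PanelValidationError(ValueError):
    """Raised when a panel violates schema or balance requirements."""


def _validate_balanced(df: pd.DataFrame, what: str) -> None:
    dup = df.duplicated(subset=["unit", "year"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise PanelValidationError(
            f"duplicate (unit, year) in {what}: ({row['unit']}, {row['year']})"
        )
    per_unit = df.groupby("unit")["year"].apply(lambda s: tuple(sorted(s)))
    if per_unit.nunique() != 1:
        raise PanelValidationError(
            f"{what} is not balanced: units observed in differing year sets"
        )


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["unit", "year"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class IndicatorPanel:
    """Balanced DMU x year panel of 3 inputs and 3 outputs, all positive."""

    data: pd.DataFrame

    REQUIRED = ["unit", "year", "region", *INPUT_COLS, *OUTPUT_COLS]

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PanelValidationError(f"missing column(s): {missing}")
        df = df[self.REQUIRED].copy()
        df["year"] = df["year"].astype(int)
        _validate_balanced(df, "indicator panel")
        vals = df[INPUT_COLS + OUTPUT_COLS]
        bad = ~(vals > 0) | vals.isna()
        if bad.any().any():
            r, c = next(
                (i, c) for c in bad.columns for i in bad.index[bad[c]]
            )
            raise PanelValidationError(
                f"nonpositive or missing indicator {c} for "
                f"(unit={df.loc[r, 'unit']}, year={df.loc[r, 'year']})"
            )
        object.__setattr__(self, "data", _canonical_sort(df))

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def cross_section(self, year: int) -> pd.DataFrame:
        """Rows of a single year, in canonical unit order."""
        sub = self.data[self.data["year"] == year]
        if sub.empty:
            raise KeyError(f"year {year} not in panel")
        return sub.reset_index(drop=True)

    def matrices(self, year: int | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (X, Y, units): input and output matrices of the frontier pool.

        ``year=None`` pools all unit-years (units labelled ``unit@year``).
        """
        if year is None:
            df = self.data
            labels = [f"{u}@{y}" for u, y in zip(df["unit"], df["year"])]
        else:
            df = self.cross_section(year)
            labels = list(df["unit"])
        return df[INPUT_COLS].to_numpy(float), df[OUTPUT_COLS].to_numpy(float), labels

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def load_indicator_panel(path: str | Path, *, repair_epsilon: float | None = None) -> IndicatorPanel:
    """Read a long-format indicator CSV (``unit,year,region,x1..x3,y1..y3``).

    Zero indicators are rejected (the slack-based measure divides by every
    input and output); ``repair_epsilon`` optionally replaces exact zeros by a
    small positive constant instead.
    """
    df = pd.read_csv(path)
    if repair_epsilon is not None:
        if repair_epsilon <= 0:
            raise ValueError("repair_epsilon must be positive")
        cols = [c for c in INPUT_COLS + OUTPUT_COLS if c in df.columns]
        df[cols] = df[cols].where(df[cols] != 0, repair_epsilon)
    return IndicatorPanel(df)


@dataclass(frozen=True)
class EfficiencyPanel:
    """Balanced unit x year panel of positive efficiency scores ``rho``.

    Scores above 1 mark super-efficient (frontier) unit-years; scores in
    (0, 1) mark inefficient ones.
    """

    data: pd.DataFrame

    REQUIRED = ["unit", "year", "region", "rho"]

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise PanelValidationError(f"missing column(s): {missing}")
        df = df[self.REQUIRED].copy()
        df["year"] = df["year"].astype(int)
        df["rho"] = df["rho"].astype(float)
        _validate_balanced(df, "efficiency panel")
        if not (df["rho"] > 0).all():
            row = df.loc[~(df["rho"] > 0)].iloc[0]
            raise PanelValidationError(
                f"nonpositive rho for (unit={row['unit']}, year={row['year']})"
            )
        object.__setattr__(self, "data", _canonical_sort(df))

    @property
    def units(self) -> list[str]:
        return sorted(self.data["unit"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def pivot(self) -> pd.DataFrame:
        """Units x years score matrix (canonical ordering)."""
        return self.data.pivot(index="unit", columns="year", values="rho")

    def subset(self, region: str) -> "EfficiencyPanel":
        """Restrict to one region ('central' or 'western')."""
        sub = self.data[self.data["region"] == region]
        if sub.empty:
            raise ValueError(f"no units in region {region!r}")
        return EfficiencyPanel(sub)

    def values_in(self, year: int, region: str = "all") -> np.ndarray:
        df = self.data if region == "all" else self.subset(region).data
        sub = df[df["year"] == year]
        if sub.empty:
            raise KeyError(f"year {year} not in panel")
        return sub["rho"].to_numpy()

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, float_format="%.6g")


def load_efficiency_csv(path: str | Path) -> EfficiencyPanel:
    """Read an efficiency CSV (``unit,year,region,rho``)."""
    return EfficiencyPanel(pd.read_csv(path))


def annual_mean(panel: EfficiencyPanel, region: str = "all") -> pd.Series:
    """Arithmetic mean score per year over all units or one region's units."""
    df = panel.data if region == "all" else panel.subset(region).data
    return df.groupby("year")["rho"].mean().rename("mean_rho")


def range_gap(panel: EfficiencyPanel) -> float:
    """Spread max(rho) - min(rho) over every unit-year in the panel."""
    return float(panel.data["rho"].max() - panel.data["rho"].min())


@dataclass
class AdjacencyMap:
    """Undirected contiguity structure over a set of units.

    ``weights`` is the row-standardized spatial weight matrix: each unit's
    neighbors receive equal weight summing to 1. Units without in-sample
    neighbors get an all-zero row and are listed in ``isolated``.
    """

    graph: nx.Graph
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(self.graph.has_edge(u, u) for u in self.graph):
            raise ValueError("self-loops are not allowed in a contiguity map")
        if not self.units:
            self.units = sorted(self.graph.nodes)
        else:
            self.units = sorted(self.units)
            self.graph.add_nodes_from(self.units)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   units: Sequence[str] | None = None) -> "AdjacencyMap":
        g = nx.Graph()
        g.add_edges_from(edges)
        return cls(g, list(units) if units is not None else [])

    @classmethod
    def from_csv(cls, path: str | Path,
                 units: Sequence[str] | None = None) -> "AdjacencyMap":
        """Read a two-column undirected edge list ``unit_a,unit_b``."""
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["unit_a", "unit_b"]:
            raise PanelValidationError(
                "adjacency CSV must have columns unit_a,unit_b"
            )
        return cls.from_edges(zip(df["unit_a"], df["unit_b"]), units)

    def restrict(self, units: Sequence[str]) -> "AdjacencyMap":
        """Drop neighbors outside ``units`` (out-of-sample contiguity)."""
        return AdjacencyMap(self.graph.subgraph(units).copy(), list(units))

    @property
    def isolated(self) -> list[str]:
        return [u for u in self.units if self.graph.degree(u) == 0]

    def neighbors(self, unit: str) -> list[str]:
        return sorted(self.graph.neighbors(unit))

    @property
    def weights(self) -> pd.DataFrame:
        """Row-standardized equal weights over in-sample neighbors."""
        w = pd.DataFrame(0.0, index=self.units, columns=self.units)
        for u in self.units:
            nbrs = self.neighbors(u)
            if nbrs:
                w.loc[u, nbrs] = 1.0 / len(nbrs)
        return w
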