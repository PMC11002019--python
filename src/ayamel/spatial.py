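"""Region-wise phenotype densities from segmented multiplex-IF cell tables.

Input is a HALO-style export: one row per segmented cell with coordinates
(micrometers), a tissue-region label (intratumor = tumor core, peritumor =
the stromal side of the invasive margin) and one binary column per marker
(positivity thresholds are applied upstream).  Region areas are explicit
inputs in mm^2.  Densities are counts of query-matching cells divided by
region area, in cells/mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MARKERS",
    "CellTable",
    "PhenotypeQuery",
    "region_density",
    "phenotype_ratio",
    "density_table",
    "read_cell_table",
    "write_cell_table",
]

MARKERS = ("CD3", "CD8", "FOXP3", "ICOS", "CD39", "PD1", "GZMB", "SOX10")
UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class PhenotypeQuery:
    """Required-positive and required-negative marker sets, e.g. CD3+SOX10-."""

    positive: frozenset[str] = frozenset()
    negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        if self.positive & self.negative:
            raise ValueError("a marker cannot be required both positive and negative")

    @classmethod
    def parse(cls, spec: str) -> "PhenotypeQuery":
        """Parse compact phenotype strings like ``"CD3+CD8-FOXP3+"``."""
        pos, neg = set(), set()
        token = ""
        for ch in spec:
            if ch == "+":
                pos.add(token); token = ""
            elif ch == "-":
                neg.add(token); token = ""
            else:
                token += ch
        if token:
            raise ValueError(f"marker {token!r} missing +/- suffix in {spec!r}")
        return cls(positive=frozenset(pos), negative=frozenset(neg))

    def mask(self, cells: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=cells.index)
        for marker in self.positive:
            m &= cells[marker] == 1
        for marker in self.negative:
            m &= cells[marker] == 0
        return m


@dataclass
class CellTable:
    """Segmented cells (x_um, y_um, region, binary marker flags) + areas.

    Cells whose region label is not in ``region_areas`` are excluded from
    every computation and counted in a QC log (mirroring the exclusion of
    necrosis, folds and staining artifacts from analysis).
    """

    cells: pd.DataFrame
    region_areas: Mapping[str, float]

    def __post_init__(self) -> None:
        self.region_areas = dict(self.region_areas)
        if any(a <= 0 for a in self.region_areas.values()):
            raise ValueError("region areas must be positive (mm^2)")
        for marker in MARKERS:
            if marker in self.cells.columns:
                vals = self.cells[marker]
                if not vals.isin((0, 1)).all():
                    raise ValueError(f"marker column {marker} must be binary 0/1")
        known = self.cells["region"].isin(self.region_areas) if len(self.cells) else pd.Series(dtype=bool)
        n_bad = int((~known).sum()) if len(self.cells) else 0
        if n_bad:
            logger.warning(
                "excluding %d cell(s) with undeclared region label(s): %s",
                n_bad, sorted(self.cells.loc[~known, "region"].unique()),
            )
            self.cells = self.cells.loc[known].reset_index(drop=True)

    @property
    def regions(self) -> list[str]:
        return list(self.region_areas)


def _region_selection(table: CellTable, region: str) -> tuple[pd.DataFrame, float]:
    if region == "total":
        return table.cells, float(sum(table.region_areas.values()))
    if region not in table.region_areas:
        raise ValueError(f"unknown region {region!r}; declared: {table.regions}")
    cells = table.cells[table.cells["region"] == region]
    return cells, float(table.region_areas[region])


def region_count(table: CellTable, query: PhenotypeQuery, region: str = "total") -> int:
    cells, _ = _region_selection(table, region)
    if cells.empty:
        return 0
    return int(query.mask(cells).sum())


def region_density(table: CellTable, query: PhenotypeQuery, region: str = "total") -> float:
    """Cells matching ``query`` in ``region``, per mm^2.

    ``region="total"`` divides the summed matching count by the summed
    declared area.
    """
    cells, area = _region_selection(table, region)
    if cells.empty:
        return 0.0
    return float(query.mask(cells).sum()) / area


def phenotype_ratio(
    table: CellTable,
    numerator: PhenotypeQuery,
    denominator: PhenotypeQuery,
    region: str = "total",
) -> float:
    """Count ratio of two phenotypes within a region (e.g. CD8:FOXP3).

    Returns NaN (flagged via log, not raised) when the denominator count
    is zero.
    """
    num = region_count(table, numerator, region)
    den = region_count(table, denominator, region)
    if den == 0:
        logger.warning("phenotype ratio undefined in %r: denominator count is 0", region)
        return float("nan")
    return num / den


def density_table(
    table: CellTable, queries: Mapping[str, PhenotypeQuery]
) -> pd.DataFrame:
    """Long-format density table: phenotype x region -> count, area, density.

    Includes a ``total`` row per phenotype.  Conservation: density x area
    summed over the declared regions equals the total matching cell count.
    """
    if not queries:
        raise ValueError("need at least one phenotype query")
    names = list(queries)
    if len(set(names)) != len(names):
        raise ValueError("duplicate phenotype names")
    rows = []
    for name, query in queries.items():
        for region in list(table.region_areas) + ["total"]:
            cells, area = _region_selection(table, region)
            count = int(query.mask(cells).sum()) if not cells.empty else 0
            rows.append(
                {"phenotype": name, "region": region, "count": count,
                 "area_mm2": area, "density": count / area}
            )
    return pd.DataFrame(rows, columns=["phenotype", "region", "count", "area_mm2", "density"])


def read_cell_table(
    path: str | Path,
    region_areas: Mapping[str, float],
    column_map: Mapping[str, str] | None = None,
) -> CellTable:
    """Read a cell CSV; ``column_map`` renames foreign (e.g. HALO) columns."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {"x_um", "y_um", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    return CellTable(cells=df, region_areas=region_areas)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    cols = ["x_um", "y_um", "region"] + [m for m in MARKERS if m in table.cells.columns]
    table.cells[cols].to_csv(path, index=False)


def write_density_table(densities: pd.DataFrame, path: str | Path) -> None:
    densities.to_csv(path, sep="\t", index=False)
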