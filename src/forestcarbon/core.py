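"""Domain types, unit handling, and tabular readers/writers shared by all stages.

The package accounts for forest biomass carbon at three geographic levels
(national, four broad regions, states), over three forest categories
(commercial state & private timberland, federal forest, sparse "other
forest"), with annual series that distinguish *missing* years from zero
values.  Everything downstream — burned-area reconstruction, burned-biomass
estimation, the NEP mass balance and the sensitivity engine — works in terms
of the containers defined here.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable

import pandas as pd
import yaml

__all__ = [
    "ACRE_TO_HECTARE",
    "AnnualSeries",
    "BurnedAreaRecord",
    "ForestCategory",
    "Geography",
    "ParseError",
    "REGION_CODES",
    "StockPoint",
    "ValidationError",
    "convert_area",
    "dm_to_carbon",
    "fsum_series",
    "load_config",
    "read_records",
    "write_records",
]

#: 1 international acre in hectares (exact definition).
ACRE_TO_HECTARE = 0.40468564224

#: The four-region partition of the contiguous study area:
#: Northeast, Southeast, Rocky Mountains, Pacific Coast.
REGION_CODES = ("NE", "SE", "RM", "PC")

GEOGRAPHY_LEVELS = ("national", "region", "state")

PROTECTION_STATES = ("protected", "unprotected", "unspecified")


class ValidationError(ValueError):
    """A value violates a domain invariant (negative area, bad fraction, ...)."""


class ParseError(ValueError):
    """A tabular input file failed validation; carries row-level detail."""

    def __init__(self, message: str, rows: list[dict] | None = None):
        super().__init__(message)
        self.rows = rows or []


class ForestCategory(str, Enum):
    """Forest land-cover category.

    ``state_private`` is almost entirely commercially used productive
    timberland; ``federal`` subsumes commercial and non-commercial forests
    under federal administration; ``other_forest`` is sparse woody
    vegetation (wood-, shrub-, scrubland).  Aggregating all three yields
    "total forest".
    """

    STATE_PRIVATE = "state_private"
    FEDERAL = "federal"
    OTHER_FOREST = "other_forest"


@dataclass(frozen=True, order=True)
class Geography:
    """A geographic accounting unit: the nation, one of four regions, or a state.

    Region codes are restricted to the fixed four-region partition
    (NE, SE, RM, PC); every state belongs to exactly one region via the
    run configuration's membership map.
    """

    level: str
    code: str

    def __post_init__(self):
        if self.level not in GEOGRAPHY_LEVELS:
            raise ValidationError(f"unknown geography level {self.level!r}")
        if self.level == "region" and self.code not in REGION_CODES:
            raise ValidationError(
                f"region code {self.code!r} not in {REGION_CODES}"
            )
        if not self.code:
            raise ValidationError("geography code must be non-empty")

    @staticmethod
    def national(code: str = "US") -> "Geography":
        return Geography("national", code)

    @staticmethod
    def region(code: str) -> "Geography":
        return Geography("region", code)

    @staticmethod
    def state(code: str) -> "Geography":
        return Geography("state", code)


def convert_area(acres: float) -> float:
    """Convert an area in acres to hectares (1 ac = 0.40468564224 ha)."""
    if acres < 0:
        raise ValidationError(f"area must be non-negative, got {acres}")
    return acres * ACRE_TO_HECTARE


def dm_to_carbon(mass: float, carbon_fraction: float = 0.5) -> float:
    """Convert dry-matter biomass (t DM) to carbon (tC).

    The default carbon content of dry matter is 50%, applied uniformly to
    fuels and stocks; it is configurable for sensitivity work.
    """
    if mass < 0:
        raise ValidationError(f"mass must be non-negative, got {mass}")
    if not 0 < carbon_fraction <= 1:
        raise ValidationError(f"carbon fraction must be in (0, 1], got {carbon_fraction}")
    return mass * carbon_fraction


def fsum_series(values: Iterable[float]) -> float:
    """Order-independent, correctly rounded sum.

    All aggregations in the pipeline (states to regions, land-cover classes
    to categories, categories to totals) go through this so that the same
    multiset of addends always yields the bit-identical total regardless of
    record order.
    """
    return math.fsum(values)


class AnnualSeries:
    """An annual time series with explicit missing years.

    Gap years are first-class: a year with no report is *never* silently
    zero-filled, because the sources genuinely distinguish "no data
    available" from "nothing burned".  ``values`` holds the defined years,
    ``gaps`` the explicitly missing ones; the two sets are disjoint.
    """

    __slots__ = ("unit", "_values", "_gaps")

    def __init__(self, unit: str, values: Mapping[int, float], gaps: Iterable[int] = ()):
        vals = {int(y): float(v) for y, v in values.items()}
        for y, v in vals.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite value {v} at year {y}")
        gapset = frozenset(int(y) for y in gaps)
        overlap = gapset & vals.keys()
        if overlap:
            raise ValidationError(f"years both defined and gap: {sorted(overlap)}")
        self.unit = unit
        self._values = dict(sorted(vals.items()))
        self._gaps = gapset

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> dict[int, float]:
        return dict(self._values)

    @property
    def gaps(self) -> frozenset[int]:
        return self._gaps

    @property
    def years(self) -> list[int]:
        """Sorted defined (non-gap) years."""
        return list(self._values)

    @property
    def span(self) -> tuple[int, int]:
        all_years = set(self._values) | self._gaps
        if not all_years:
            raise ValidationError("empty series has no span")
        return min(all_years), max(all_years)

    def get(self, year: int, default=None):
        return self._values.get(year, default)

    def __contains__(self, year: int) -> bool:
        return year in self._values

    def __len__(self) -> int:
        return len(self._values)

    def items(self):
        return self._values.items()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AnnualSeries)
            and self.unit == other.unit
            and self._values == other._values
            and self._gaps == other._gaps
        )

    def __repr__(self) -> str:
        y0, y1 = self.span if (self._values or self._gaps) else (None, None)
        return (
            f"AnnualSeries(unit={self.unit!r}, {len(self._values)} years"
            f" [{y0}..{y1}], {len(self._gaps)} gaps)"
        )

    # -- transforms --------------------------------------------------------
    def restrict(self, start: int, end: int) -> "AnnualSeries":
        """Closed-interval restriction to [start, end]."""
        return AnnualSeries(
            self.unit,
            {y: v for y, v in self._values.items() if start <= y <= end},
            {y for y in self._gaps if start <= y <= end},
        )

    def map_values(self, fn: Callable[[float], float], unit: str | None = None) -> "AnnualSeries":
        return AnnualSeries(unit or self.unit, {y: fn(v) for y, v in self._values.items()}, self._gaps)

    def scale(self, factor: float, unit: str | None = None) -> "AnnualSeries":
        return self.map_values(lambda v: v * factor, unit=unit)

    def with_gaps(self, extra_gaps: Iterable[int]) -> "AnnualSeries":
        """Force the given years to be gaps, dropping any defined values there."""
        extra = frozenset(int(y) for y in extra_gaps)
        return AnnualSeries(
            self.unit,
            {y: v for y, v in self._values.items() if y not in extra},
            self._gaps | extra,
        )

    def to_pandas(self) -> pd.Series:
        """Render as a pandas Series over the full span, gaps as NaN."""
        y0, y1 = self.span
        idx = range(y0, y1 + 1)
        return pd.Series(
            [self._values.get(y, float("nan")) for y in idx],
            index=idx,
            name=self.unit,
        )

    @staticmethod
    def from_pandas(s: pd.Series, unit: str) -> "AnnualSeries":
        values = {int(y): float(v) for y, v in s.items() if pd.notna(v)}
        gaps = {int(y) for y, v in s.items() if pd.isna(v)}
        return AnnualSeries(unit, values, gaps)


def combine_series(
    a: AnnualSeries,
    b: AnnualSeries,
    fn: Callable[[float, float], float],
    unit: str | None = None,
) -> AnnualSeries:
    """Pointwise binary combination over years defined in both series.

    A year that is a gap or absent in either input is a gap in the output
    (over the union span); gap semantics propagate, never impute.
    """
    years = set(a.values) & set(b.values)
    all_years = (set(a.values) | a.gaps) & (set(b.values) | b.gaps) | (a.gaps | b.gaps)
    gaps = {y for y in all_years if y not in years}
    return AnnualSeries(unit or a.unit, {y: fn(a.get(y), b.get(y)) for y in years}, gaps)


@dataclass(frozen=True)
class BurnedAreaRecord:
    """One source's report of area burned for a year x geography x category."""

    year: int
    geography: Geography
    category: ForestCategory
    protection: str
    area: float
    source: str

    def __post_init__(self):
        if self.area < 0:
            raise ValidationError(
                f"burned area must be non-negative, got {self.area} "
                f"({self.geography.code} {self.year})"
            )
        if self.protection not in PROTECTION_STATES:
            raise ValidationError(f"unknown protection status {self.protection!r}")

    @property
    def key(self) -> tuple:
        return (self.year, self.geography, self.category, self.protection, self.source)


@dataclass(frozen=True)
class StockPoint:
    """Inventory-time forest area and biomass carbon stock for a geography.

    ``total_stock`` must equal ``forest_area * stock_density`` to 1e-6
    relative tolerance; it may be omitted (computed) at construction.
    """

    time: int
    geography: Geography
    forest_area: float
    stock_density: float
    total_stock: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.forest_area < 0 or self.stock_density < 0:
            raise ValidationError("stock point values must be non-negative")
        expected = self.forest_area * self.stock_density
        if self.total_stock is None:
            object.__setattr__(self, "total_stock", expected)
        elif not math.isclose(self.total_stock, expected, rel_tol=1e-6, abs_tol=1e-9):
            raise ValidationError(
                f"total_stock {self.total_stock} inconsistent with "
                f"area x density = {expected} at {self.geography.code} {self.time}"
            )


# ---------------------------------------------------------------------------
# Tabular I/O
#
# All record kinds interchange as UTF-8 comma-separated text with a mandatory
# header row and "." decimal mark.  Missing values are empty cells and surface
# as gaps, never as zero.  Reals are written with repr-level precision so a
# write-then-read round trip is lossless.
# ---------------------------------------------------------------------------

_BURNED_AREA_COLUMNS = ["year", "level", "code", "category", "protection", "area", "source"]
_STOCK_COLUMNS = ["time", "level", "code", "forest_area", "stock_density", "total_stock"]

_SCHEMAS = {"burned_area": _BURNED_AREA_COLUMNS, "stock_point": _STOCK_COLUMNS}


def _format_float(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_records(records: Iterable, path: str | Path, schema: str) -> None:
    """Write typed records as delimited text (see module docstring dialect)."""
    path = Path(path)
    if schema == "burned_area":
        rows = [
            {
                "year": r.year,
                "level": r.geography.level,
                "code": r.geography.code,
                "category": r.category.value,
                "protection": r.protection,
                "area": _format_float(r.area),
                "source": r.source,
            }
            for r in records
        ]
        cols = _BURNED_AREA_COLUMNS
    elif schema == "stock_point":
        rows = [
            {
                "time": r.time,
                "level": r.geography.level,
                "code": r.geography.code,
                "forest_area": _format_float(r.forest_area),
                "stock_density": _format_float(r.stock_density),
                "total_stock": _format_float(r.total_stock),
            }
            for r in records
        ]
        cols = _STOCK_COLUMNS
    else:
        raise ValidationError(f"unknown record schema {schema!r}")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, encoding="utf-8")


def read_records(path: str | Path, schema: str) -> list:
    """Read and validate typed records; reject rows with structured errors.

    Raises :class:`ParseError` naming every offending row (1-based data-row
    numbers) on unknown columns, non-numeric or negative values, and
    duplicate keys.
    """
    path = Path(path)
    if schema not in _SCHEMAS:
        raise ValidationError(f"unknown record schema {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    expected = _SCHEMAS[schema]
    if list(df.columns) != expected:
        raise ParseError(
            f"{path}: header {list(df.columns)} does not match schema "
            f"{schema!r} columns {expected}"
        )
    errors: list[dict] = []
    records = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            if schema == "burned_area":
                rec = BurnedAreaRecord(
                    year=int(row.year),
                    geography=Geography(row.level, row.code),
                    category=ForestCategory(row.category),
                    protection=row.protection,
                    area=float(row.area),
                    source=row.source,
                )
                key = rec.key
            else:
                rec = StockPoint(
                    time=int(row.time),
                    geography=Geography(row.level, row.code),
                    forest_area=float(row.forest_area),
                    stock_density=float(row.stock_density),
                    total_stock=float(row.total_stock),
                )
                key = (rec.time, rec.geography)
            if key in seen:
                raise ValidationError(f"duplicate key {key}")
            seen.add(key)
            records.append(rec)
        except (ValueError, ValidationError) as exc:
            errors.append({"row": i, "error": str(exc)})
    if errors:
        detail = "; ".join(f"row {e['row']}: {e['error']}" for e in errors[:5])
        raise ParseError(f"{path}: {len(errors)} invalid row(s): {detail}", rows=errors)
    return records


def write_annual_series(series: AnnualSeries, path: str | Path, value_name: str = "value") -> None:
    """Write an annual series as year,value text; gap years have empty cells."""
    y0, y1 = series.span
    rows = []
    for y in range(y0, y1 + 1):
        if y in series:
            rows.append({"year": y, value_name: _format_float(series.get(y))})
        elif y in series.gaps:
            rows.append({"year": y, value_name: ""})
    pd.DataFrame(rows, columns=["year", value_name]).to_csv(path, index=False, encoding="utf-8")


def read_annual_series(path: str | Path, unit: str, value_name: str = "value") -> AnnualSeries:
    df = pd.read_csv(path, encoding="utf-8")
    if "year" not in df.columns or value_name not in df.columns:
        raise ParseError(f"{path}: expected columns ['year', {value_name!r}]")
    values, gaps = {}, set()
    for _, row in df.iterrows():
        y = int(row["year"])
        if pd.isna(row[value_name]):
            gaps.add(y)
        else:
            values[y] = float(row[value_name])
    return AnnualSeries(unit, values, gaps)


def load_config(path: str | Path) -> dict:
    """Load a nestable key-value run configuration (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return cfg
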