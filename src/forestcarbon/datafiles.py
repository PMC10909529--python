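"""On-disk interchange for rendered source bundles and pipeline outputs.

Everything is UTF-8 comma-separated text with a header row plus one YAML
metadata file; reals are written with repr-level precision so a round trip
through disk is lossless.  This is the layer the command-line stages use to
hand data to each other.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .balance import BalanceInterval, ExpansionFactors, ProductRatios
from .biomass import FuelCompartment, FuelProfile
from .core import (
    AnnualSeries,
    ForestCategory,
    Geography,
    ParseError,
    StockPoint,
    read_records,
    write_records,
)
from .reconstruction import SourceSeries
from .synthetic import RenderedSources, SyntheticWorld, WorldConfig

__all__ = [
    "config_from_dict",
    "config_to_dict",
    "read_sources",
    "write_balances",
    "write_reconstruction",
    "write_sources",
    "write_truth",
]


def _fmt(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


# ---------------------------------------------------------------------------
# WorldConfig <-> plain dict (for YAML configs and the manifest hash)
# ---------------------------------------------------------------------------

_ENUM_KEY_FIELDS = {
    "category_shares": ForestCategory,
    "underreporting": ForestCategory,
    "base_loads": FuelCompartment,
    "other_forest_loads": FuelCompartment,
    "completeness_means": FuelCompartment,
}
_EXPANSION_FIELDS = ("expansion_central", "expansion_min", "expansion_max")


def config_to_dict(cfg: WorldConfig) -> dict:
    out: dict = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if f.name in _ENUM_KEY_FIELDS:
            out[f.name] = {k.value: val for k, val in v.items()}
        elif f.name in _EXPANSION_FIELDS:
            out[f.name] = {
                cls: dataclasses.asdict(getattr(v, cls)) for cls in ("fuelwood", "industrial")
            }
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def config_from_dict(d: dict) -> WorldConfig:
    kwargs = dict(d)
    for name, enum_cls in _ENUM_KEY_FIELDS.items():
        if name in kwargs and kwargs[name] is not None:
            kwargs[name] = {enum_cls(k): float(v) for k, v in kwargs[name].items()}
    for name in _EXPANSION_FIELDS:
        if name in kwargs and isinstance(kwargs[name], dict):
            kwargs[name] = ExpansionFactors(
                fuelwood=ProductRatios(**kwargs[name]["fuelwood"]),
                industrial=ProductRatios(**kwargs[name]["industrial"]),
            )
    for f in dataclasses.fields(WorldConfig):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    if kwargs.get("excluded_window") is not None:
        kwargs["excluded_window"] = tuple(kwargs["excluded_window"])
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(WorldConfig)}
    if unknown:
        raise ParseError(f"unknown world-config keys: {sorted(unknown)}")
    return WorldConfig(**kwargs)


# ---------------------------------------------------------------------------
# Rendered source bundle <-> directory of delimited files
# ---------------------------------------------------------------------------


def _series_rows(series: AnnualSeries, key: dict, value_name: str) -> list[dict]:
    rows = []
    y0, y1 = series.span
    for y in range(y0, y1 + 1):
        if y in series:
            rows.append({**key, "year": y, value_name: _fmt(series.get(y))})
        elif y in series.gaps:
            rows.append({**key, "year": y, value_name: ""})
    return rows


def _frame_rows(frames: dict[str, pd.DataFrame], value_name: str) -> pd.DataFrame:
    rows = []
    for region in sorted(frames):
        df = frames[region]
        for year in df.index:
            for col in df.columns:
                rows.append(
                    {"region": region, "year": int(year), "compartment": col,
                     value_name: _fmt(float(df.at[year, col]))}
                )
    return pd.DataFrame(rows)


def _read_frames(path: Path, value_name: str) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path, encoding="utf-8")
    out = {}
    for region, sub in df.groupby("region"):
        out[str(region)] = sub.pivot(index="year", columns="compartment", values=value_name)[
            [c.value for c in FuelCompartment]
        ]
    return out


def write_sources(sources: RenderedSources, outdir: str | Path) -> list[Path]:
    """Write a rendered bundle as a directory of delimited files + meta.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame):
        p = outdir / name
        df.to_csv(p, index=False, encoding="utf-8")
        written.append(p)

    emit("census.csv", pd.DataFrame(_series_rows(sources.census.series, {}, "area_ha")))
    write_records(sources.agency_records, outdir / "agency_records.csv", "burned_area")
    written.append(outdir / "agency_records.csv")
    emit(
        "regional_totals.csv",
        pd.DataFrame(
            [
                row
                for r in sorted(sources.regional_totals)
                for row in _series_rows(sources.regional_totals[r], {"region": r}, "area_ha")
            ]
        ),
    )
    emit(
        "landsat_classes.csv",
        pd.DataFrame(
            [
                {"year": y, "state": s, "class": cls, "ownership": own, "area_ha": _fmt(v)}
                for (y, s, cls, own), v in sorted(sources.landsat_classes.items())
            ]
        ),
    )
    emit(
        "fuel_profiles.csv",
        pd.DataFrame(
            [
                {"table": table, "region": r, "category": cat.value,
                 "compartment": comp.value, "load_t_dm_ha": _fmt(load)}
                for table, profs in (
                    ("field", sources.field_profiles),
                    ("modeled", sources.modeled_profiles),
                )
                for r in sorted(profs)
                for cat, p in sorted(profs[r].items(), key=lambda kv: kv[0].value)
                for comp, load in sorted(p.loads.items(), key=lambda kv: kv[0].value)
            ]
        ),
    )
    emit("coefficients.csv", _frame_rows(sources.coefficients, "coefficient"))
    emit("completeness.csv", _frame_rows(sources.modeled_completeness, "completeness"))
    emit(
        "severity.csv",
        pd.DataFrame(
            [
                {"mode": mode, "region": r, "compartment": c.value, "completeness": _fmt(v)}
                for mode in sorted(sources.severity)
                for r in sorted(sources.severity[mode])
                for c, v in sorted(sources.severity[mode][r].items(), key=lambda kv: kv[0].value)
            ]
        ),
    )
    emit(
        "harvest_stem.csv",
        pd.DataFrame(
            [
                row
                for g in sorted(sources.harvest_stem)
                for row in _series_rows(sources.harvest_stem[g], {"geography": g}, "stem_tc")
            ]
        ),
    )
    emit("fuelwood_share.csv", pd.DataFrame(_series_rows(sources.fuelwood_share, {}, "share")))
    emit(
        "grazing.csv",
        pd.DataFrame(
            [
                row
                for g in sorted(sources.grazing)
                for row in _series_rows(sources.grazing[g], {"geography": g}, "grazing_tc")
            ]
        ),
    )
    stock_records = [s for g in sorted(sources.stocks) for s in sources.stocks[g]]
    write_records(stock_records, outdir / "stocks.csv", "stock_point")
    written.append(outdir / "stocks.csv")

    meta = {
        "config": config_to_dict(sources.config),
        "areas": dict(sources.areas),
        "expansion": {
            name: {
                cls: dataclasses.asdict(getattr(sources.expansion[name], cls))
                for cls in ("fuelwood", "industrial")
            }
            for name in sources.expansion
        },
        "grazing_range": list(sources.grazing_range),
    }
    with open(outdir / "meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    written.append(outdir / "meta.yaml")
    return written


def _series_from_rows(df: pd.DataFrame, value_name: str, unit: str) -> AnnualSeries:
    values, gaps = {}, set()
    for _, row in df.iterrows():
        y = int(row["year"])
        if pd.isna(row[value_name]):
            gaps.add(y)
        else:
            values[y] = float(row[value_name])
    return AnnualSeries(unit, values, gaps)


def read_sources(indir: str | Path) -> RenderedSources:
    """Read a source bundle written by :func:`write_sources`."""
    indir = Path(indir)
    with open(indir / "meta.yaml", "r", encoding="utf-8") as fh:
        meta = yaml.safe_load(fh)
    cfg = config_from_dict(meta["config"])

    census = SourceSeries(
        source="census",
        geography=Geography.national(),
        category_scope=frozenset(ForestCategory),
        series=_series_from_rows(pd.read_csv(indir / "census.csv"), "area_ha", "ha"),
    )
    agency_records = read_records(indir / "agency_records.csv", "burned_area")

    rt = pd.read_csv(indir / "regional_totals.csv")
    regional_totals = {
        str(r): _series_from_rows(sub, "area_ha", "ha") for r, sub in rt.groupby("region")
    }

    lc = pd.read_csv(indir / "landsat_classes.csv")
    landsat = {
        (int(row["year"]), str(row["state"]), str(row["class"]), str(row["ownership"])): float(
            row["area_ha"]
        )
        for _, row in lc.iterrows()
    }

    fp = pd.read_csv(indir / "fuel_profiles.csv")
    profiles: dict[str, dict] = {"field": {}, "modeled": {}}
    for (table, region, category), sub in fp.groupby(["table", "region", "category"]):
        loads = {
            FuelCompartment(row["compartment"]): float(row["load_t_dm_ha"])
            for _, row in sub.iterrows()
        }
        profiles[str(table)].setdefault(str(region), {})[ForestCategory(category)] = FuelProfile(
            Geography.region(str(region)), ForestCategory(category), loads, cfg.reference_period
        )

    coefficients = _read_frames(indir / "coefficients.csv", "coefficient")
    completeness = _read_frames(indir / "completeness.csv", "completeness")

    sv = pd.read_csv(indir / "severity.csv")
    severity: dict[str, dict[str, dict[FuelCompartment, float]]] = {}
    for (mode, region), sub in sv.groupby(["mode", "region"]):
        severity.setdefault(str(mode), {})[str(region)] = {
            FuelCompartment(row["compartment"]): float(row["completeness"])
            for _, row in sub.iterrows()
        }

    hs = pd.read_csv(indir / "harvest_stem.csv")
    harvest_stem = {
        str(g): _series_from_rows(sub, "stem_tc", "tC/yr") for g, sub in hs.groupby("geography")
    }
    fuelwood_share = _series_from_rows(
        pd.read_csv(indir / "fuelwood_share.csv"), "share", "fraction"
    )
    gz = pd.read_csv(indir / "grazing.csv")
    grazing = {
        str(g): _series_from_rows(sub, "grazing_tc", "tC/yr") for g, sub in gz.groupby("geography")
    }

    stock_records = read_records(indir / "stocks.csv", "stock_point")
    stocks: dict[str, list[StockPoint]] = {}
    for s in stock_records:
        code = "US" if s.geography.level == "national" else s.geography.code
        stocks.setdefault(code, []).append(s)
    for g in stocks:
        stocks[g].sort(key=lambda s: s.time)

    expansion = {
        name: ExpansionFactors(
            fuelwood=ProductRatios(**meta["expansion"][name]["fuelwood"]),
            industrial=ProductRatios(**meta["expansion"][name]["industrial"]),
        )
        for name in meta["expansion"]
    }
    return RenderedSources(
        config=cfg,
        census=census,
        agency_records=agency_records,
        regional_totals=regional_totals,
        landsat_classes=landsat,
        field_profiles=profiles["field"],
        modeled_profiles=profiles["modeled"],
        coefficients=coefficients,
        modeled_completeness=completeness,
        severity=severity,
        harvest_stem=harvest_stem,
        fuelwood_share=fuelwood_share,
        grazing=grazing,
        expansion=expansion,
        grazing_range=tuple(meta["grazing_range"]),
        stocks=stocks,
        areas={str(k): float(v) for k, v in meta["areas"].items()},
    )


def write_truth(world: SyntheticWorld, outdir: str | Path) -> list[Path]:
    """Write the ground-truth tables of a synthetic world."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    df = pd.DataFrame(
        [
            {"year": y, "state": s, "category": c.value, "area_ha": _fmt(v)}
            for (y, s, c), v in sorted(
                world.burned_atoms.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
            )
        ]
    )
    p = outdir / "burned_area_truth.csv"
    df.to_csv(p, index=False, encoding="utf-8")
    written.append(p)
    rows = []
    for g in world.geographies:
        for b in world.true_balances[g]:
            rows.append(
                {
                    "geography": g, "t0": b.t0, "t1": b.t1,
                    "stock_change_rate": _fmt(b.stock_change_rate),
                    "fire": _fmt(b.fire), "harvest": _fmt(b.harvest),
                    "grazing": _fmt(b.grazing), "nep": _fmt(b.nep),
                    "denominator_area": _fmt(b.denominator_area),
                }
            )
    p = outdir / "balance_truth.csv"
    pd.DataFrame(rows).to_csv(p, index=False, encoding="utf-8")
    written.append(p)
    return written


def write_reconstruction(result, outdir: str | Path) -> list[Path]:
    """Write national/regional series, provenance and diagnostics tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "national_burned_area.csv"
    pd.DataFrame(
        [
            {
                "year": y,
                "area_ha": _fmt(result.national.get(y)),
                "source": result.provenance.get(y, ""),
            }
            for y in result.national.years
        ]
    ).to_csv(p, index=False, encoding="utf-8")
    written.append(p)
    rows = []
    for r in sorted(result.regional):
        for cat in ForestCategory:
            series = result.regional[r][cat]
            y0, y1 = series.span
            for y in range(y0, y1 + 1):
                if y in series:
                    rows.append(
                        {"region": r, "category": cat.value, "year": y,
                         "area_ha": _fmt(series.get(y))}
                    )
                elif y in series.gaps:
                    rows.append({"region": r, "category": cat.value, "year": y, "area_ha": ""})
    p = outdir / "regional_burned_area.csv"
    pd.DataFrame(rows).to_csv(p, index=False, encoding="utf-8")
    written.append(p)
    p = outdir / "diagnostics.csv"
    pd.DataFrame(result.diagnostics).to_csv(p, index=False, encoding="utf-8")
    written.append(p)
    return written


def write_balances(
    balances: dict[str, list[BalanceInterval]],
    averages: dict[str, BalanceInterval],
    outdir: str | Path,
) -> list[Path]:
    """One table per geography: intervals plus a period-average row."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for g in sorted(balances):
        rows = []
        for b in balances[g] + [averages[g]]:
            rows.append(
                {
                    "t0": b.t0, "t1": b.t1,
                    "stock_change_rate": _fmt(b.stock_change_rate),
                    "fire": _fmt(b.fire), "harvest": _fmt(b.harvest),
                    "grazing": _fmt(b.grazing), "nep": _fmt(b.nep),
                    "denominator_area": _fmt(b.denominator_area),
                }
            )
        rows[-1]["kind"] = "period_average"
        p = outdir / f"balance_{g}.csv"
        pd.DataFrame(rows).to_csv(p, index=False, encoding="utf-8")
        written.append(p)
    return written
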