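"""Seeded generator of synthetic carbon-accounting "worlds".

A world is a complete ground truth — burned area by year x state x
category, fuel timelines, removal fluxes, stock trajectories — constructed
so that the NEP mass-balance identity holds exactly: stock density evolves
as the prescribed NEP minus generated removals, so recovering the
prescription from the rendered inputs is a sharp test of every pipeline
stage.  The world is then rendered into the multi-source input families the
reconstruction consumes (a national statistical compilation, state agency
tables with missing years and a discontinued category, regional published
totals, satellite land-cover class tables), with configurable reporting
noise, underreporting and coverage gaps.

The default configuration is history-shaped: a 92-year span, four regions,
strongly declining fire in the east, a mid-century harvest peak and eastern
stock recovery.  It is a plausible world for documentation and smoke tests,
not a claim of reproducing real magnitudes.

Reported burned areas are rounded to whole hectares, as the historical
sources do; a convenient consequence is that aggregation and subtraction of
reported values are exact in floating point, so exact-recovery checks are
bit-clean.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .balance import (
    BalanceInterval,
    ExpansionFactors,
    ProductRatios,
    RemovalSeries,
    compute_balances,
    expand_harvest,
)
from .biomass import (
    FuelCompartment,
    FuelProfile,
    FuelTimeline,
    allocate_fuels,
    build_fuel_timeline,
    burned_biomass,
    extrapolate_pre_span,
)
from .core import (
    AnnualSeries,
    BurnedAreaRecord,
    ForestCategory,
    Geography,
    StockPoint,
    ValidationError,
    fsum_series,
)
from .reconstruction import SourceSeries

__all__ = [
    "RenderedSources",
    "SyntheticWorld",
    "WorldConfig",
    "generate_world",
    "recovery_report",
    "render_sources",
]

DEFAULT_MEMBERSHIP = {
    "ME": "NE", "NY": "NE", "PA": "NE",
    "FL": "SE", "GA": "SE", "MS": "SE",
    "MT": "RM", "ID": "RM", "CO": "RM",
    "CA": "PC", "OR": "PC", "WA": "PC",
}

_C = FuelCompartment

DEFAULT_BASE_LOADS = {
    _C.DUFF_LITTER: 15.0,
    _C.DEAD_1HR: 0.5,
    _C.DEAD_10HR: 1.5,
    _C.DEAD_100HR: 3.0,
    _C.DEAD_1000HR: 8.0,
    _C.HERB: 0.3,
    _C.CANOPY: 45.0,
}

DEFAULT_OTHER_FOREST_LOADS = {
    _C.DUFF_LITTER: 4.0,
    _C.DEAD_1HR: 0.8,
    _C.HERB: 1.2,
}

DEFAULT_COMPLETENESS_MEANS = {
    _C.DUFF_LITTER: 0.80,
    _C.DEAD_1HR: 0.90,
    _C.DEAD_10HR: 0.60,
    _C.DEAD_100HR: 0.40,
    _C.DEAD_1000HR: 0.20,
    _C.HERB: 0.95,
    _C.CANOPY: 0.25,
}


def _default_expansion(scale: float) -> ExpansionFactors:
    return ExpansionFactors(
        fuelwood=ProductRatios(0.12 * scale, 0.25 * scale, 0.26 * scale),
        industrial=ProductRatios(0.11 * scale, 0.20 * scale, 0.24 * scale),
    )


@dataclass
class WorldConfig:
    """Full parameterization of a synthetic world.

    Sizes, trends and noise levels default to the history-shaped conditions
    (span, four regions, excluded window 1980-1984, the listed regional
    missing years, census-to-satellite switch in 1985).  Reporting noise
    defaults to zero because the real sources agree to within a few
    percent; year-to-year variability lives in the truth process instead.
    """

    seed: int
    span: tuple[int, int] = (1926, 2017)
    membership: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MEMBERSHIP))
    region_area: dict[str, float] = field(
        default_factory=lambda: {"NE": 30e6, "SE": 80e6, "RM": 60e6, "PC": 80e6}
    )
    # source coverage
    switch_year: int = 1985
    census_span: tuple[int, int] = (1926, 1984)
    agency_span: tuple[int, int] = (1941, 1985)
    agency_missing_years: tuple[int, ...] = (1943, 1944, 1952, 1953, 1957, 1959, 1967, 1968, 1970)
    state_private_reported_until: int = 1960
    regional_totals_span: tuple[int, int] = (1938, 1979)
    regional_totals_include_other: bool = True
    excluded_window: tuple[int, int] | None = (1980, 1984)
    # burned-area truth process
    state_base_burn: dict[str, float] = field(
        default_factory=lambda: {"NE": 1.5e5, "SE": 1.5e6, "RM": 2.5e5, "PC": 3.5e5}
    )
    fire_decline_rate: float = 0.03
    fire_process_sd: float = 0.4
    category_shares: dict[ForestCategory, float] = field(
        default_factory=lambda: {
            ForestCategory.STATE_PRIVATE: 0.80,
            ForestCategory.FEDERAL: 0.12,
            ForestCategory.OTHER_FOREST: 0.08,
        }
    )
    # reporting model
    reporting_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"census": 0.0, "usfs": 0.0, "regional": 0.0, "landsat": 0.0}
    )
    underreporting: dict[ForestCategory, float] = field(default_factory=dict)
    # fuels
    modeled_start: int = 1941
    reference_period: tuple[int, int] = (2003, 2015)
    base_loads: dict[FuelCompartment, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_LOADS)
    )
    other_forest_loads: dict[FuelCompartment, float] = field(
        default_factory=lambda: dict(DEFAULT_OTHER_FOREST_LOADS)
    )
    region_fuel_multiplier: dict[str, float] = field(
        default_factory=lambda: {"NE": 0.9, "SE": 1.0, "RM": 1.1, "PC": 1.3}
    )
    federal_fuel_multiplier: float = 1.1
    modeled_fuel_offset: float = 0.92
    coefficient_sd: float = 0.05
    coefficient_trend: float = 0.002
    completeness_means: dict[FuelCompartment, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLETENESS_MEANS)
    )
    completeness_jitter_sd: float = 0.02
    severity_scales: dict[str, float] = field(
        default_factory=lambda: {"low": 0.5, "moderate": 1.0, "high": 1.6}
    )
    carbon_fraction: float = 0.5
    # removals
    harvest_peak: float = 1.1e8
    harvest_peak_year: int = 1970
    harvest_width: float = 70.0
    harvest_noise_sd: float = 0.05
    harvest_region_share: dict[str, float] = field(
        default_factory=lambda: {"NE": 0.15, "SE": 0.35, "RM": 0.15, "PC": 0.35}
    )
    fuelwood_share_start: float = 0.5
    fuelwood_share_end: float = 0.1
    grazing_base: float = 1.5e7
    grazing_decline_rate: float = 0.02
    grazing_noise_sd: float = 0.05
    expansion_central: ExpansionFactors = field(default_factory=lambda: _default_expansion(1.0))
    expansion_min: ExpansionFactors = field(default_factory=lambda: _default_expansion(0.7))
    expansion_max: ExpansionFactors = field(default_factory=lambda: _default_expansion(1.4))
    grazing_range: tuple[float, float] = (1.0 / 4.2, 1.7)
    # stocks and NEP prescription
    nep_base: dict[str, float] = field(
        default_factory=lambda: {"US": 1.4, "NE": 1.3, "SE": 1.8, "RM": 0.9, "PC": 1.5}
    )
    nep_trend: float = 0.3
    initial_density: dict[str, float] = field(
        default_factory=lambda: {"US": 35.0, "NE": 40.0, "SE": 30.0, "RM": 45.0, "PC": 60.0}
    )
    national_inventory_years: tuple[int, ...] = (
        1926, 1930, 1940, 1950, 1960, 1970, 1977, 1987, 1997, 2007, 2017,
    )
    regional_inventory_years: tuple[int, ...] = (
        1940, 1950, 1960, 1970, 1977, 1987, 1997, 2007, 2017,
    )
    denominator_mode: str = "mean"

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for u in self.underreporting.values():
            if not 0.0 <= u <= 1.0:
                raise ValidationError(f"underreporting fraction must be in [0, 1], got {u}")
        for sd in self.reporting_noise_sd.values():
            if sd < 0:
                raise ValidationError("reporting noise sd must be non-negative")
        y0, y1 = self.span
        for t in self.national_inventory_years + self.regional_inventory_years:
            if not y0 <= t <= y1:
                raise ValidationError(f"inventory year {t} outside span {self.span}")
        if len(self.national_inventory_years) < 2:
            raise ValidationError("need at least two inventory points")

    @property
    def regions(self) -> list[str]:
        return sorted(set(self.membership.values()))

    @property
    def states(self) -> list[str]:
        return sorted(self.membership)

    def replace(self, **kwargs) -> "WorldConfig":
        return dataclasses.replace(self, **kwargs)

    def complete_coverage(self) -> "WorldConfig":
        """Variant with no missing years, no excluded window, and regional
        published totals running up to the satellite switch, so every
        regional year is recoverable."""
        return self.replace(
            agency_missing_years=(),
            excluded_window=None,
            regional_totals_span=(self.regional_totals_span[0], self.switch_year - 1),
        )


@dataclass
class SyntheticWorld:
    """Ground truth plus everything derived from it."""

    config: WorldConfig
    burned_atoms: dict[tuple[int, str, ForestCategory], float]
    national_truth: AnnualSeries
    regional_truth: dict[str, dict[ForestCategory, AnnualSeries]]
    regional_total_truth: dict[str, AnnualSeries]
    field_profiles: dict[str, dict[ForestCategory, FuelProfile]]
    modeled_profiles: dict[str, dict[ForestCategory, FuelProfile]]
    coefficients: dict[str, pd.DataFrame]
    modeled_completeness: dict[str, pd.DataFrame]
    severity: dict[str, dict[str, dict[FuelCompartment, float]]]
    timelines: dict[str, dict[ForestCategory, FuelTimeline]]
    national_timeline: FuelTimeline
    harvest_stem: dict[str, AnnualSeries]
    fuelwood_share: AnnualSeries
    removals: dict[str, dict[str, RemovalSeries]]
    fire_biomass: dict[str, AnnualSeries]
    density: dict[str, AnnualSeries]
    prescribed_nep: dict[str, AnnualSeries]
    stocks: dict[str, list[StockPoint]]
    true_balances: dict[str, list[BalanceInterval]]
    areas: dict[str, float]

    @property
    def geographies(self) -> list[str]:
        return ["US"] + self.config.regions


def _geo(code: str) -> Geography:
    return Geography.national() if code == "US" else Geography.region(code)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(6)
    names = ("fire", "coefficients", "completeness", "harvest", "grazing", "reporting")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def national_fuel_timeline(
    timelines: dict[str, dict[ForestCategory, FuelTimeline]],
    region_weights: dict[str, float],
    category_mix: dict[ForestCategory, float],
) -> FuelTimeline:
    """National-scale fuel terms as region-area x category-mix weighted sums.

    Loads are the weighted sum of allocated per-category loads (absent
    compartments count as zero); completeness is the region-area weighted
    mean.  Used when only aggregate national burned area exists.
    """
    wtot = fsum_series(region_weights.values())
    cols = [c.value for c in FuelCompartment]
    loads = None
    cc = None
    for r in sorted(timelines):
        w = region_weights[r] / wtot
        for cat, share in sorted(category_mix.items(), key=lambda kv: kv[0].value):
            part = timelines[r][cat].loads.reindex(columns=cols, fill_value=0.0)
            loads = part * (w * share) if loads is None else loads + part * (w * share)
        cc_part = timelines[r][ForestCategory.STATE_PRIVATE].completeness.reindex(
            columns=cols, fill_value=0.0
        )
        cc = cc_part * w if cc is None else cc + cc_part * w
    return FuelTimeline(Geography.national(), loads, cc)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Deterministically generate a full synthetic world from its config."""
    y0, y1 = config.span
    years = list(range(y0, y1 + 1))
    nyears = len(years)
    rng = _streams(config.seed)

    # --- burned-area truth: declining trend with lognormal year-to-year
    # variation, split into categories, rounded to whole hectares ----------
    atoms: dict[tuple[int, str, ForestCategory], float] = {}
    cat_order = sorted(config.category_shares, key=lambda c: c.value)
    for state in config.states:
        region = config.membership[state]
        base = config.state_base_burn[region]
        z = rng["fire"].standard_normal(nyears)
        for i, y in enumerate(years):
            total = base * np.exp(-config.fire_decline_rate * (y - y0))
            total *= np.exp(config.fire_process_sd * z[i])
            for cat in cat_order:
                atoms[(y, state, cat)] = float(round(total * config.category_shares[cat]))

    regional_truth: dict[str, dict[ForestCategory, AnnualSeries]] = {}
    regional_total_truth: dict[str, AnnualSeries] = {}
    for r in config.regions:
        member_states = [s for s in config.states if config.membership[s] == r]
        regional_truth[r] = {
            cat: AnnualSeries(
                "ha",
                {y: fsum_series(atoms[(y, s, cat)] for s in member_states) for y in years},
            )
            for cat in cat_order
        }
        regional_total_truth[r] = AnnualSeries(
            "ha",
            {
                y: fsum_series(atoms[(y, s, c)] for s in member_states for c in cat_order)
                for y in years
            },
        )
    national_truth = AnnualSeries(
        "ha",
        {
            y: fsum_series(atoms[(y, s, c)] for s in config.states for c in cat_order)
            for y in years
        },
    )

    # --- fuels: field profiles, modeled alternatives, change coefficients,
    # completeness, severity tables ----------------------------------------
    field_profiles: dict[str, dict[ForestCategory, FuelProfile]] = {}
    modeled_profiles: dict[str, dict[ForestCategory, FuelProfile]] = {}
    for r in config.regions:
        mult = config.region_fuel_multiplier[r]
        per_cat = {}
        for cat in cat_order:
            if cat is ForestCategory.OTHER_FOREST:
                loads = {c: v * mult for c, v in config.other_forest_loads.items()}
            else:
                fed = config.federal_fuel_multiplier if cat is ForestCategory.FEDERAL else 1.0
                loads = {c: v * mult * fed for c, v in config.base_loads.items()}
            per_cat[cat] = FuelProfile(_geo(r), cat, loads, config.reference_period)
        field_profiles[r] = per_cat
        modeled_profiles[r] = {
            cat: FuelProfile(
                _geo(r),
                cat,
                {c: v * config.modeled_fuel_offset for c, v in p.loads.items()},
                config.reference_period,
            )
            for cat, p in per_cat.items()
        }

    model_years = pd.Index(range(config.modeled_start, y1 + 1), name="year")
    cols = [c.value for c in FuelCompartment]
    coefficients: dict[str, pd.DataFrame] = {}
    modeled_completeness: dict[str, pd.DataFrame] = {}
    for r in config.regions:
        z = rng["coefficients"].standard_normal((len(model_years), len(cols)))
        trend = 1.0 + config.coefficient_trend * (
            np.asarray(model_years) - config.modeled_start
        )
        coefficients[r] = pd.DataFrame(
            np.exp(config.coefficient_sd * z) * trend[:, None], index=model_years, columns=cols
        )
        zc = rng["completeness"].standard_normal((len(model_years), len(cols)))
        means = np.array([config.completeness_means[FuelCompartment(c)] for c in cols])
        modeled_completeness[r] = pd.DataFrame(
            np.clip(means[None, :] + config.completeness_jitter_sd * zc, 0.01, 0.99),
            index=model_years,
            columns=cols,
        )

    severity: dict[str, dict[str, dict[FuelCompartment, float]]] = {}
    for mode, scale in config.severity_scales.items():
        severity[mode] = {
            r: {
                c: float(np.clip(config.completeness_means[c] * scale, 0.01, 0.99))
                for c in FuelCompartment
            }
            for r in config.regions
        }

    # central timelines: field loads scaled by modeled coefficients,
    # modeled completeness; extrapolated back to the span start
    timelines: dict[str, dict[ForestCategory, FuelTimeline]] = {}
    for r in config.regions:
        timelines[r] = {}
        for cat in cat_order:
            profile = field_profiles[r][cat]
            allocated = FuelProfile(
                profile.region, cat, allocate_fuels(profile, cat), profile.reference_period
            )
            tl = build_fuel_timeline(allocated, coefficients[r], modeled_completeness[r])
            timelines[r][cat] = extrapolate_pre_span(tl, config.modeled_start, y0)

    category_mix = dict(config.category_shares)
    national_timeline = national_fuel_timeline(timelines, config.region_area, category_mix)

    # --- removals ----------------------------------------------------------
    zh = rng["harvest"].standard_normal(nyears)
    stem_national = AnnualSeries(
        "tC/yr",
        {
            y: config.harvest_peak
            * float(
                np.exp(-(((y - config.harvest_peak_year) / config.harvest_width) ** 2))
                * np.exp(config.harvest_noise_sd * zh[i])
            )
            for i, y in enumerate(years)
        },
    )
    harvest_stem = {"US": stem_national}
    for r in config.regions:
        share = config.harvest_region_share[r]
        harvest_stem[r] = stem_national.map_values(lambda v, s=share: v * s)
    fuelwood_share = AnnualSeries(
        "fraction",
        {
            y: config.fuelwood_share_start
            + (config.fuelwood_share_end - config.fuelwood_share_start) * (y - y0) / (y1 - y0)
            for y in years
        },
    )

    zg = rng["grazing"].standard_normal(nyears)
    grazing_national_vals = {
        y: config.grazing_base
        * float(
            np.exp(-config.grazing_decline_rate * (y - y0)) * np.exp(config.grazing_noise_sd * zg[i])
        )
        for i, y in enumerate(years)
    }
    area_total = fsum_series(config.region_area.values())
    grazing = {"US": AnnualSeries("tC/yr", grazing_national_vals)}
    for r in config.regions:
        w = config.region_area[r] / area_total
        grazing[r] = grazing["US"].map_values(lambda v, w=w: v * w)

    # fire removal: central burned biomass per geography
    fire_biomass: dict[str, AnnualSeries] = {}
    for r in config.regions:
        pieces = [
            burned_biomass(
                regional_truth[r][cat], timelines[r][cat], cat, config.carbon_fraction
            ).series
            for cat in cat_order
        ]
        fire_biomass[r] = AnnualSeries(
            "tC", {y: fsum_series(p.get(y) for p in pieces) for y in pieces[0].years}
        )
    fire_biomass["US"] = burned_biomass(
        national_truth, national_timeline, None, config.carbon_fraction
    ).series

    removals: dict[str, dict[str, RemovalSeries]] = {}
    for g in ["US"] + config.regions:
        removals[g] = {
            "fire": RemovalSeries(_geo(g), "fire", fire_biomass[g].scale(1.0, unit="tC/yr")),
            "harvest": expand_harvest(
                harvest_stem[g], config.expansion_central, fuelwood_share, _geo(g)
            ),
            "grazing": RemovalSeries(_geo(g), "grazing", grazing[g]),
        }

    # --- stocks: density integrates prescribed NEP minus removals ----------
    areas = {"US": area_total, **config.region_area}
    density: dict[str, AnnualSeries] = {}
    prescribed: dict[str, AnnualSeries] = {}
    stocks: dict[str, list[StockPoint]] = {}
    true_balances: dict[str, list[BalanceInterval]] = {}
    for g in ["US"] + config.regions:
        inv = (
            config.national_inventory_years if g == "US" else config.regional_inventory_years
        )
        start = inv[0]
        nep_series = AnnualSeries(
            "tC/ha/yr",
            {
                y: config.nep_base[g] * (1.0 + config.nep_trend * (y - y0) / (y1 - y0))
                for y in years
            },
        )
        prescribed[g] = nep_series
        d = {start: config.initial_density[g]}
        for y in range(start + 1, y1 + 1):
            removal_pa = (
                fsum_series(removals[g][c].series.get(y) for c in ("fire", "harvest", "grazing"))
                / areas[g]
            )
            d[y] = d[y - 1] + nep_series.get(y) - removal_pa
            if d[y] < 0:
                raise ValidationError(
                    f"prescribed NEP too low: density of {g} negative in {y}"
                )
        density[g] = AnnualSeries("tC/ha", d)
        stocks[g] = [
            StockPoint(time=t, geography=_geo(g), forest_area=areas[g], stock_density=d[t])
            for t in inv
        ]
        intervals = list(zip(inv[:-1], inv[1:]))
        true_balances[g] = compute_balances(
            stocks[g], removals[g], intervals, config.denominator_mode
        )

    return SyntheticWorld(
        config=config,
        burned_atoms=atoms,
        national_truth=national_truth,
        regional_truth=regional_truth,
        regional_total_truth=regional_total_truth,
        field_profiles=field_profiles,
        modeled_profiles=modeled_profiles,
        coefficients=coefficients,
        modeled_completeness=modeled_completeness,
        severity=severity,
        timelines=timelines,
        national_timeline=national_timeline,
        harvest_stem=harvest_stem,
        fuelwood_share=fuelwood_share,
        removals=removals,
        fire_biomass=fire_biomass,
        density=density,
        prescribed_nep=prescribed,
        stocks=stocks,
        true_balances=true_balances,
        areas=areas,
    )


# ---------------------------------------------------------------------------
# Rendering: truth -> multi-source input families
# ---------------------------------------------------------------------------


@dataclass
class RenderedSources:
    """Everything the pipeline consumes, as one in-memory bundle.

    Burned-area families carry the configured coverage, noise and
    underreporting; the remaining tables (fuels, removals inputs, stocks)
    pass through from the truth, as they are inputs to the study, not
    estimated by it.
    """

    config: WorldConfig
    census: SourceSeries
    agency_records: list[BurnedAreaRecord]
    regional_totals: dict[str, AnnualSeries]
    landsat_classes: dict[tuple[int, str, str, str], float]
    field_profiles: dict[str, dict[ForestCategory, FuelProfile]]
    modeled_profiles: dict[str, dict[ForestCategory, FuelProfile]]
    coefficients: dict[str, pd.DataFrame]
    modeled_completeness: dict[str, pd.DataFrame]
    severity: dict[str, dict[str, dict[FuelCompartment, float]]]
    harvest_stem: dict[str, AnnualSeries]
    fuelwood_share: AnnualSeries
    grazing: dict[str, AnnualSeries]
    expansion: dict[str, ExpansionFactors]
    grazing_range: tuple[float, float]
    stocks: dict[str, list[StockPoint]]
    areas: dict[str, float]


def _noise_factor(rng: np.random.Generator, sd: float) -> float:
    if sd == 0.0:
        return 1.0
    return float(np.exp(sd * rng.standard_normal()))


def render_sources(world: SyntheticWorld, config: WorldConfig | None = None) -> RenderedSources:
    """Render a world into its multi-source input files (in memory).

    Deterministic for a fixed seed: the reporting-noise stream is split off
    the same root seed, so re-rendering yields identical sources.
    """
    config = config or world.config
    y0, y1 = config.span
    rng = _streams(config.seed)["reporting"]
    sd = {k: config.reporting_noise_sd.get(k, 0.0) for k in ("census", "usfs", "regional", "landsat")}
    under = {cat: config.underreporting.get(cat, 0.0) for cat in ForestCategory}
    cat_order = sorted(ForestCategory, key=lambda c: c.value)

    def reported(atom_key) -> float:
        v = world.burned_atoms[atom_key]
        u = under[atom_key[2]]
        return v - u * v if u else v

    # national statistical series (census-style), full early coverage
    census_vals = {}
    for y in range(config.census_span[0], config.census_span[1] + 1):
        v = fsum_series(
            reported((y, s, c)) for s in config.states for c in cat_order
        )
        census_vals[y] = v * _noise_factor(rng, sd["census"])
    census = SourceSeries(
        source="census",
        geography=Geography.national(),
        category_scope=frozenset(ForestCategory),
        series=AnnualSeries("ha", census_vals),
    )

    # state agency tables: missing years, state&private discontinued
    missing = set(config.agency_missing_years)
    agency_records: list[BurnedAreaRecord] = []
    for y in range(config.agency_span[0], config.agency_span[1] + 1):
        if y in missing:
            continue
        for s in config.states:
            for cat in cat_order:
                if (
                    cat is ForestCategory.STATE_PRIVATE
                    and y > config.state_private_reported_until
                ):
                    continue
                agency_records.append(
                    BurnedAreaRecord(
                        year=y,
                        geography=Geography.state(s),
                        category=cat,
                        protection="unspecified",
                        area=reported((y, s, cat)) * _noise_factor(rng, sd["usfs"]),
                        source="usfs",
                    )
                )

    # regional published totals
    regional_totals: dict[str, AnnualSeries] = {}
    for r in config.regions:
        member_states = [s for s in config.states if config.membership[s] == r]
        scope = list(cat_order)
        if not config.regional_totals_include_other:
            scope = [c for c in scope if c is not ForestCategory.OTHER_FOREST]
        vals = {}
        for y in range(config.regional_totals_span[0], config.regional_totals_span[1] + 1):
            v = fsum_series(reported((y, s, c)) for s in member_states for c in scope)
            vals[y] = v * _noise_factor(rng, sd["regional"])
        regional_totals[r] = AnnualSeries("ha", vals)

    # satellite land-cover class tables; forest categories split into
    # classes with power-of-two fractions so class sums are exact
    landsat: dict[tuple[int, str, str, str], float] = {}
    for y in range(config.switch_year, y1 + 1):
        for s in config.states:
            f = _noise_factor(rng, sd["landsat"])
            state_total = 0.0
            for cat in (ForestCategory.STATE_PRIVATE, ForestCategory.FEDERAL):
                v = reported((y, s, cat)) * f
                state_total += v
                landsat[(y, s, "deciduous", cat.value)] = v / 2
                landsat[(y, s, "evergreen", cat.value)] = v / 4
                landsat[(y, s, "mixed", cat.value)] = v / 4
            v = reported((y, s, ForestCategory.OTHER_FOREST)) * f
            landsat[(y, s, "shrub_scrub", "aggregated")] = v
            # herbaceous burns exist in the class table but are excluded
            # from forest accounting downstream
            landsat[(y, s, "herbaceous", "aggregated")] = round(0.15 * (state_total + v))

    return RenderedSources(
        config=config,
        census=census,
        agency_records=agency_records,
        regional_totals=regional_totals,
        landsat_classes=landsat,
        field_profiles=world.field_profiles,
        modeled_profiles=world.modeled_profiles,
        coefficients=world.coefficients,
        modeled_completeness=world.modeled_completeness,
        severity=world.severity,
        harvest_stem=world.harvest_stem,
        fuelwood_share=world.fuelwood_share,
        grazing={g: world.removals[g]["grazing"].series for g in world.geographies},
        expansion={
            "central": config.expansion_central,
            "min": config.expansion_min,
            "max": config.expansion_max,
        },
        grazing_range=config.grazing_range,
        stocks=world.stocks,
        areas=world.areas,
    )


def recovery_report(world: SyntheticWorld, result) -> dict:
    """Error metrics of a pipeline run against the world's ground truth.

    Reports RMSE and bias for the national and regional burned-area series,
    the national burned-biomass series, and interval NEP per geography.
    ``result`` is a :class:`forestcarbon.pipeline.PipelineResult`.
    """

    def series_err(est: AnnualSeries, truth: AnnualSeries) -> dict:
        years = sorted(set(est.values) & set(truth.values))
        if not years:
            raise ValidationError("no overlapping years between estimate and truth")
        diffs = [est.get(y) - truth.get(y) for y in years]
        return {
            "rmse": float(np.sqrt(fsum_series(d * d for d in diffs) / len(diffs))),
            "bias": fsum_series(diffs) / len(diffs),
            "n_years": len(years),
        }

    report: dict = {
        "burned_area": {"US": series_err(result.reconstruction.national, world.national_truth)}
    }
    for r in world.config.regions:
        est = result.reconstruction.regional_total(r)
        report["burned_area"][r] = series_err(est, world.regional_total_truth[r])
    report["burned_biomass"] = {
        "US": series_err(result.fire_biomass["US"].series, world.fire_biomass["US"])
    }
    report["nep"] = {}
    for g in world.geographies:
        true_by_interval = {(b.t0, b.t1): b.nep for b in world.true_balances[g]}
        diffs = [
            b.nep - true_by_interval[(b.t0, b.t1)]
            for b in result.balances[g]
            if (b.t0, b.t1) in true_by_interval
        ]
        if diffs:
            report["nep"][g] = {
                "rmse": float(np.sqrt(fsum_series(d * d for d in diffs) / len(diffs))),
                "bias": fsum_series(diffs) / len(diffs),
                "n_intervals": len(diffs),
            }
    return report
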