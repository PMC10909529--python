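"""Factorial sensitivity engine: variant family and min/max envelopes.

Uncertainty is represented factorially, not probabilistically: burned
biomass is re-estimated under every combination of fuel-load source (field
measured vs. modeled), fuel dynamics (static reference-period loads vs.
dynamic coefficient-scaled loads) and a static literature-derived severity
completeness set (low, moderate, high).  The four main (source x dynamics)
variations times three severity sub-variants, over the four regions, give
the canonical 48 regional series.  Envelopes are pointwise minima/maxima
over variants; the central estimate (modeled-dynamic fuels with modeled
completeness) is reported alongside, never clipped into, the envelope.

Harvest uncertainty is spanned by minimum/maximum biomass expansion
factors; the grazing range is an input band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .balance import ExpansionFactors, RemovalSeries, expand_harvest
from .biomass import (
    BurnedBiomassSeries,
    FuelCompartment,
    FuelProfile,
    FuelTimeline,
    build_fuel_timeline,
    burned_biomass,
    static_timeline,
)
from .core import AnnualSeries, ForestCategory, Geography, ValidationError, fsum_series

__all__ = [
    "Envelope",
    "RangeSummary",
    "SensitivityInputs",
    "VariantSpec",
    "enumerate_variants",
    "envelope",
    "harvest_envelope",
    "range_summary",
    "run_variant",
]

FUEL_SOURCES = ("field_measured", "modeled")
FUEL_DYNAMICS = ("static", "dynamic")
CC_MODES = ("low", "moderate", "high")


@dataclass(frozen=True)
class VariantSpec:
    """One cell of the factorial design.

    The four (fuel_source x fuel_dynamics) combinations are the main
    variations; the three severity modes are the sub-variants.
    """

    fuel_source: str
    fuel_dynamics: str
    cc_mode: str
    region: Geography

    def __post_init__(self):
        if self.fuel_source not in FUEL_SOURCES:
            raise ValidationError(f"unknown fuel source {self.fuel_source!r}")
        if self.fuel_dynamics not in FUEL_DYNAMICS:
            raise ValidationError(f"unknown fuel dynamics {self.fuel_dynamics!r}")
        if self.cc_mode not in CC_MODES:
            raise ValidationError(f"unknown severity mode {self.cc_mode!r}")


@dataclass
class Envelope:
    """Pointwise min/max band over sensitivity variants for one component."""

    central: AnnualSeries
    low: AnnualSeries
    high: AnnualSeries
    component: str


@dataclass
class RangeSummary:
    """Deviations of the envelope around the central estimate.

    ``mean_plus``/``mean_minus`` are the mean yearly deviations
    (high - central, low - central); ``max_plus``/``min_minus`` the yearly
    extremes.  Units follow the input series.
    """

    mean_plus: float
    mean_minus: float
    max_plus: float
    min_minus: float


@dataclass
class SensitivityInputs:
    """Everything one variant run needs, keyed by region code."""

    field_profiles: dict[str, dict[ForestCategory, FuelProfile]]
    modeled_profiles: dict[str, dict[ForestCategory, FuelProfile]]
    coefficients: dict[str, pd.DataFrame]
    modeled_completeness: dict[str, pd.DataFrame]
    severity_completeness: dict[str, dict[str, dict[FuelCompartment, float]]]
    burned_area: dict[str, dict[ForestCategory, AnnualSeries]]
    span: tuple[int, int]
    carbon_fraction: float = 0.5


def enumerate_variants(regions: list[Geography]) -> list[VariantSpec]:
    """Full Cartesian product (source x dynamics) x severity x regions.

    Deterministic order; four regions yield the canonical 48 variants.
    """
    if not regions:
        raise ValidationError("need at least one region")
    if len(set(regions)) != len(regions):
        raise ValidationError("duplicate regions in variant enumeration")
    return [
        VariantSpec(src, dyn, cc, region)
        for src, dyn, cc, region in itertools.product(
            FUEL_SOURCES, FUEL_DYNAMICS, CC_MODES, regions
        )
    ]


def _severity_frame(
    severity: dict[FuelCompartment, float], like: pd.DataFrame
) -> pd.DataFrame:
    return pd.DataFrame(
        {c: [severity[FuelCompartment(c)]] * len(like.index) for c in like.columns},
        index=like.index,
    )


def run_variant(
    spec: VariantSpec,
    inputs: SensitivityInputs,
    exclude_duff: bool = False,
    average_loads: bool = False,
    aggregated_area: bool = False,
) -> BurnedBiomassSeries:
    """Re-estimate one region's burned biomass under a variant spec.

    Optional toggles outside the canonical 48: ``exclude_duff`` drops the
    duff/litter compartment; ``average_loads`` uses the across-category mean
    profile for every category; ``aggregated_area`` applies that mean
    profile to the summed total-forest burned area instead of per category.
    """
    code = spec.region.code
    profiles = (
        inputs.field_profiles if spec.fuel_source == "field_measured" else inputs.modeled_profiles
    )
    if code not in profiles:
        raise ValidationError(f"no {spec.fuel_source} fuel table for region {code!r}")
    if code not in inputs.severity_completeness.get(spec.cc_mode, {}):
        raise ValidationError(f"missing {spec.cc_mode!r} severity table for region {code!r}")
    severity = inputs.severity_completeness[spec.cc_mode][code]
    per_cat = profiles[code]
    if average_loads or aggregated_area:
        per_cat = {cat: _mean_profile(per_cat) for cat in per_cat}

    compartments = frozenset(FuelCompartment)
    if exclude_duff:
        compartments = compartments - {FuelCompartment.DUFF_LITTER}

    def timeline_for(profile: FuelProfile) -> FuelTimeline:
        if spec.fuel_dynamics == "static":
            return static_timeline(profile, severity, inputs.span)
        tl = build_fuel_timeline(
            profile,
            inputs.coefficients[code],
            inputs.modeled_completeness[code],
            span=inputs.span,
        )
        return FuelTimeline(tl.region, tl.loads, _severity_frame(severity, tl.loads))

    area_by_cat = inputs.burned_area[code]
    if aggregated_area:
        total_area = _sum_series(list(area_by_cat.values()))
        profile = next(iter(per_cat.values()))
        result = burned_biomass(
            total_area,
            timeline_for(profile),
            None,
            inputs.carbon_fraction,
            compartments=compartments,
        )
        return BurnedBiomassSeries(spec.region, None, result.series)

    pieces = []
    for cat, area in sorted(area_by_cat.items(), key=lambda kv: kv[0].value):
        cat_comps = compartments
        if cat is ForestCategory.OTHER_FOREST:
            from .biomass import OTHER_FOREST_COMPARTMENTS

            cat_comps = compartments & OTHER_FOREST_COMPARTMENTS
        pieces.append(
            burned_biomass(
                area,
                timeline_for(per_cat[cat]),
                cat,
                inputs.carbon_fraction,
                compartments=cat_comps,
            ).series
        )
    return BurnedBiomassSeries(spec.region, None, _sum_series(pieces))


def _mean_profile(per_cat: dict[ForestCategory, FuelProfile]) -> FuelProfile:
    profiles = list(per_cat.values())
    comps = set().union(*(p.loads.keys() for p in profiles))
    loads = {
        c: fsum_series(p.loads.get(c, 0.0) for p in profiles) / len(profiles) for c in comps
    }
    return FuelProfile(
        region=profiles[0].region,
        category=profiles[0].category,
        loads=loads,
        reference_period=profiles[0].reference_period,
    )


def _sum_series(series_list: list[AnnualSeries]) -> AnnualSeries:
    years = set.intersection(*(set(s.values) for s in series_list))
    all_years = set()
    for s in series_list:
        all_years |= set(s.values) | s.gaps
    return AnnualSeries(
        series_list[0].unit,
        {y: fsum_series(s.get(y) for s in series_list) for y in years},
        {y for y in all_years if y not in years},
    )


def envelope(variants: list[BurnedBiomassSeries | AnnualSeries], central) -> Envelope:
    """Pointwise min/max over variant series; the central estimate passes
    through unclipped."""
    if not variants:
        raise ValidationError("empty variant list")
    series = [v.series if isinstance(v, BurnedBiomassSeries) else v for v in variants]
    if len(series) < 2:
        raise ValidationError("need at least two variants for an envelope")
    central_series = central.series if isinstance(central, BurnedBiomassSeries) else central
    years = set.intersection(*(set(s.values) for s in series))
    if not years:
        raise ValidationError("variants share no common defined years")
    all_years = set()
    for s in series:
        all_years |= set(s.values) | s.gaps
    gaps = {y for y in all_years if y not in years}
    unit = series[0].unit
    low = AnnualSeries(unit, {y: min(s.get(y) for s in series) for y in years}, gaps)
    high = AnnualSeries(unit, {y: max(s.get(y) for s in series) for y in years}, gaps)
    return Envelope(central=central_series, low=low, high=high, component="fire")


def range_summary(env: Envelope) -> RangeSummary:
    """Mean and extreme yearly deviations of the envelope around the central
    estimate, in the series' own unit."""
    years = sorted(set(env.central.values) & set(env.low.values) & set(env.high.values))
    if not years:
        raise ValidationError("central and envelope series share no defined years")
    span_mismatch = set(env.low.values) ^ set(env.high.values)
    if span_mismatch:
        raise ValidationError(f"low/high span mismatch at years {sorted(span_mismatch)}")
    plus = [env.high.get(y) - env.central.get(y) for y in years]
    minus = [env.low.get(y) - env.central.get(y) for y in years]
    return RangeSummary(
        mean_plus=fsum_series(plus) / len(plus),
        mean_minus=fsum_series(minus) / len(minus),
        max_plus=max(plus),
        min_minus=min(minus),
    )


def harvest_envelope(
    stem: AnnualSeries,
    central: ExpansionFactors,
    minimum: ExpansionFactors,
    maximum: ExpansionFactors,
    fuelwood_share: AnnualSeries | float,
    geography: Geography,
) -> Envelope:
    """Harvest uncertainty band from minimum/central/maximum expansion factors."""
    runs = {
        name: expand_harvest(stem, f, fuelwood_share, geography).series
        for name, f in (("low", minimum), ("central", central), ("high", maximum))
    }
    env = envelope([runs["low"], runs["high"]], runs["central"])
    env.component = "harvest"
    return env
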