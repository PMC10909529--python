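"""End-to-end pipeline: reconstruction -> burned biomass -> balance -> sensitivity.

Consumes a :class:`forestcarbon.synthetic.RenderedSources` bundle (whether
generated in memory or read back from disk) and produces the reconstructed
series, central burned-biomass estimates, removal fluxes, interval balances
with period averages and cumulative offsets, and — optionally — the full
factorial sensitivity family with envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .balance import (
    BalanceInterval,
    RemovalSeries,
    compute_balances,
    cumulative_offsets,
    expand_harvest,
    period_average_balance,
)
from .biomass import (
    BurnedBiomassSeries,
    FuelProfile,
    allocate_fuels,
    build_fuel_timeline,
    burned_biomass,
    extrapolate_pre_span,
)
from .core import AnnualSeries, ForestCategory, Geography, ValidationError, fsum_series
from .reconstruction import (
    ReconstructionResult,
    SourceSeries,
    aggregate_landcover_classes,
    aggregate_states_to_regions,
    infer_missing_state_private,
    moving_average,
    splice_national,
)
from .sensitivity import (
    Envelope,
    RangeSummary,
    SensitivityInputs,
    VariantSpec,
    enumerate_variants,
    envelope,
    harvest_envelope,
    range_summary,
    run_variant,
)
from .synthetic import RenderedSources, national_fuel_timeline

__all__ = ["PipelineResult", "SensitivityResult", "run_pipeline", "reconstruct", "LANDSAT_CLASS_MAP"]

#: Satellite land-cover classes: the three forest classes resolve to a
#: category via the ownership column; shrub/scrub maps to other forest;
#: herbaceous (non-forest) burns are excluded from forest accounting.
LANDSAT_CLASS_MAP = {
    "deciduous": "forest",
    "evergreen": "forest",
    "mixed": "forest",
    "shrub_scrub": ForestCategory.OTHER_FOREST,
}
LANDSAT_EXCLUDED = frozenset({"herbaceous", "agricultural"})


@dataclass
class SensitivityResult:
    variants: dict[VariantSpec, AnnualSeries]
    fire_envelope: Envelope
    fire_summary: RangeSummary
    harvest_envelope: Envelope
    grazing_envelope: Envelope
    combined_envelope: Envelope


@dataclass
class PipelineResult:
    reconstruction: ReconstructionResult
    national_smoothed: AnnualSeries
    fire_biomass: dict[str, BurnedBiomassSeries]
    removals: dict[str, dict[str, RemovalSeries]]
    balances: dict[str, list[BalanceInterval]]
    period_averages: dict[str, BalanceInterval]
    offsets: dict[str, dict[str, float]]
    sensitivity: SensitivityResult | None = None
    diagnostics: list[dict] = field(default_factory=list)


def _geo(code: str) -> Geography:
    return Geography.national() if code == "US" else Geography.region(code)


def reconstruct(sources: RenderedSources) -> ReconstructionResult:
    """Build the continuous national and regional burned-area series.

    National: the statistical compilation up to the switch year, satellite
    data from it onward.  Regional, per category: agency tables where
    reported; the discontinued state & private component backed out of the
    regional published totals by subtraction; satellite class aggregates
    from the switch year; the excluded window and listed missing years stay
    gaps.
    """
    cfg = sources.config
    y0, y1 = cfg.span
    diagnostics: list[dict] = []

    sat_records, excluded_report = aggregate_landcover_classes(
        sources.landsat_classes, LANDSAT_CLASS_MAP, LANDSAT_EXCLUDED
    )
    diagnostics.extend(excluded_report)

    sat_national = SourceSeries(
        source="landsat",
        geography=Geography.national(),
        category_scope=frozenset(ForestCategory),
        series=AnnualSeries(
            "ha",
            {
                y: fsum_series(r.area for r in sat_records if r.year == y)
                for y in range(cfg.switch_year, y1 + 1)
            },
        ),
    )
    splice = splice_national(sources.census, sat_national, cfg.switch_year)
    diagnostics.extend(splice.diagnostics)

    agency_region = aggregate_states_to_regions(
        sources.agency_records, cfg.membership, span=cfg.agency_span
    )
    sat_region = aggregate_states_to_regions(
        sat_records, cfg.membership, span=(cfg.switch_year, y1)
    )

    excluded = set()
    if cfg.excluded_window is not None:
        excluded = set(range(cfg.excluded_window[0], cfg.excluded_window[1] + 1))

    regional: dict[str, dict[ForestCategory, AnnualSeries]] = {}
    for r in cfg.regions:
        # covered components for the subtraction: every category the
        # published totals include except the one being inferred
        covered_cats = [ForestCategory.FEDERAL]
        if cfg.regional_totals_include_other:
            covered_cats.append(ForestCategory.OTHER_FOREST)
        cov_series = [agency_region[r][c] for c in covered_cats]
        cov_years = set.intersection(*(set(s.values) for s in cov_series))
        covered = AnnualSeries(
            "ha",
            {y: fsum_series(s.get(y) for s in cov_series) for y in cov_years},
            frozenset.union(*(s.gaps for s in cov_series)) - cov_years,
        )
        inferred, clamps = infer_missing_state_private(sources.regional_totals[r], covered)
        for c in clamps:
            diagnostics.append({**c, "region": r})

        regional[r] = {}
        for cat in ForestCategory:
            values: dict[int, float] = {}
            gaps: set[int] = set()
            for y in range(cfg.agency_span[0], y1 + 1):
                if y in excluded:
                    gaps.add(y)
                    if y in agency_region[r][cat] or y in sat_region[r][cat]:
                        diagnostics.append(
                            {"event": "excluded_window", "year": y, "region": r,
                             "category": cat.value}
                        )
                    continue
                if y >= cfg.switch_year and y in sat_region[r][cat]:
                    values[y] = sat_region[r][cat].get(y)
                elif y < cfg.switch_year and y in agency_region[r][cat]:
                    values[y] = agency_region[r][cat].get(y)
                elif (
                    cat is ForestCategory.STATE_PRIVATE
                    and y < cfg.switch_year
                    and y in inferred
                ):
                    values[y] = inferred.get(y)
                else:
                    gaps.add(y)
            regional[r][cat] = AnnualSeries("ha", values, gaps)

    return ReconstructionResult(
        national=splice.series,
        regional=regional,
        provenance=splice.provenance,
        diagnostics=diagnostics,
    )


def _central_timelines(sources: RenderedSources):
    """Central fuel timelines per region x category: field-measured loads,
    dynamic modeled coefficients, modeled completeness, back-extrapolated."""
    cfg = sources.config
    timelines = {}
    for r in cfg.regions:
        timelines[r] = {}
        for cat in ForestCategory:
            profile = sources.field_profiles[r][cat]
            allocated = FuelProfile(
                profile.region, cat, allocate_fuels(profile, cat), profile.reference_period
            )
            tl = build_fuel_timeline(
                allocated, sources.coefficients[r], sources.modeled_completeness[r]
            )
            timelines[r][cat] = extrapolate_pre_span(tl, cfg.modeled_start, cfg.span[0])
    return timelines


def _sum_defined(series_list: list[AnnualSeries], unit: str) -> AnnualSeries:
    years = set.intersection(*(set(s.values) for s in series_list))
    all_years = set()
    for s in series_list:
        all_years |= set(s.values) | s.gaps
    return AnnualSeries(
        unit,
        {y: fsum_series(s.get(y) for s in series_list) for y in years},
        {y for y in all_years if y not in years},
    )


def run_pipeline(sources: RenderedSources, with_sensitivity: bool = True) -> PipelineResult:
    """Run every stage on a rendered source bundle."""
    cfg = sources.config
    recon = reconstruct(sources)
    smoothed = moving_average(recon.national, window=5)

    timelines = _central_timelines(sources)
    national_tl = national_fuel_timeline(timelines, cfg.region_area, dict(cfg.category_shares))

    fire_biomass: dict[str, BurnedBiomassSeries] = {}
    for r in cfg.regions:
        pieces = [
            burned_biomass(recon.regional[r][cat], timelines[r][cat], cat, cfg.carbon_fraction).series
            for cat in ForestCategory
        ]
        fire_biomass[r] = BurnedBiomassSeries(
            _geo(r), None, _sum_defined(pieces, "tC"),
            per_area=_sum_defined(pieces, "tC").map_values(
                lambda v, a=sources.areas[r]: v / a, unit="tC/ha"
            ),
        )
    nat = burned_biomass(recon.national, national_tl, None, cfg.carbon_fraction)
    fire_biomass["US"] = BurnedBiomassSeries(
        Geography.national(), None, nat.series,
        per_area=nat.series.map_values(lambda v: v / sources.areas["US"], unit="tC/ha"),
    )

    removals: dict[str, dict[str, RemovalSeries]] = {}
    balances: dict[str, list[BalanceInterval]] = {}
    averages: dict[str, BalanceInterval] = {}
    offsets: dict[str, dict[str, float]] = {}
    for g in ["US"] + cfg.regions:
        removals[g] = {
            "fire": RemovalSeries(_geo(g), "fire", fire_biomass[g].series.scale(1.0, unit="tC/yr")),
            "harvest": expand_harvest(
                sources.harvest_stem[g], sources.expansion["central"],
                sources.fuelwood_share, _geo(g),
            ),
            "grazing": RemovalSeries(_geo(g), "grazing", sources.grazing[g]),
        }
        inv = cfg.national_inventory_years if g == "US" else cfg.regional_inventory_years
        intervals = list(zip(inv[:-1], inv[1:]))
        balances[g] = compute_balances(
            sources.stocks[g], removals[g], intervals, cfg.denominator_mode
        )
        averages[g] = period_average_balance(balances[g])
        offsets[g] = cumulative_offsets(balances[g])

    sens = _run_sensitivity(sources, recon, fire_biomass, removals) if with_sensitivity else None

    return PipelineResult(
        reconstruction=recon,
        national_smoothed=smoothed,
        fire_biomass=fire_biomass,
        removals=removals,
        balances=balances,
        period_averages=averages,
        offsets=offsets,
        sensitivity=sens,
        diagnostics=recon.diagnostics,
    )


def _run_sensitivity(
    sources: RenderedSources,
    recon: ReconstructionResult,
    fire_biomass: dict[str, BurnedBiomassSeries],
    removals: dict[str, dict[str, RemovalSeries]],
) -> SensitivityResult:
    cfg = sources.config
    inputs = SensitivityInputs(
        field_profiles=sources.field_profiles,
        modeled_profiles=sources.modeled_profiles,
        coefficients=sources.coefficients,
        modeled_completeness=sources.modeled_completeness,
        severity_completeness=sources.severity,
        burned_area={r: recon.regional[r] for r in cfg.regions},
        span=(cfg.modeled_start, cfg.span[1]),
        carbon_fraction=cfg.carbon_fraction,
    )
    specs = enumerate_variants([Geography.region(r) for r in cfg.regions])
    variants = {spec: run_variant(spec, inputs).series for spec in specs}

    # national variant series: sum the matching regional variants
    by_cell: dict[tuple[str, str, str], list[AnnualSeries]] = {}
    for spec, series in variants.items():
        by_cell.setdefault((spec.fuel_source, spec.fuel_dynamics, spec.cc_mode), []).append(series)
    national_variants = [_sum_defined(v, "tC") for v in by_cell.values()]
    central_regional = _sum_defined([fire_biomass[r].series for r in cfg.regions], "tC")

    fire_env = envelope(national_variants, central_regional)
    to_tg = lambda env, comp: Envelope(
        central=env.central.scale(1e-6, unit="TgC/yr"),
        low=env.low.scale(1e-6, unit="TgC/yr"),
        high=env.high.scale(1e-6, unit="TgC/yr"),
        component=comp,
    )
    fire_env_tg = to_tg(fire_env, "fire")

    harv_env = harvest_envelope(
        sources.harvest_stem["US"],
        sources.expansion["central"],
        sources.expansion["min"],
        sources.expansion["max"],
        sources.fuelwood_share,
        Geography.national(),
    )
    harv_env_tg = to_tg(harv_env, "harvest")

    gz = sources.grazing["US"]
    lo_f, hi_f = sources.grazing_range
    gz_env = Envelope(
        central=gz.scale(1e-6, unit="TgC/yr"),
        low=gz.scale(lo_f * 1e-6, unit="TgC/yr"),
        high=gz.scale(hi_f * 1e-6, unit="TgC/yr"),
        component="grazing",
    )

    def env_sum(envs: list[Envelope]) -> Envelope:
        return Envelope(
            central=_sum_defined([e.central for e in envs], "TgC/yr"),
            low=_sum_defined([e.low for e in envs], "TgC/yr"),
            high=_sum_defined([e.high for e in envs], "TgC/yr"),
            component="total",
        )

    combined = env_sum([fire_env_tg, harv_env_tg, gz_env])
    return SensitivityResult(
        variants=variants,
        fire_envelope=fire_env_tg,
        fire_summary=range_summary(fire_env_tg),
        harvest_envelope=harv_env_tg,
        grazing_envelope=gz_env,
        combined_envelope=combined,
    )
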