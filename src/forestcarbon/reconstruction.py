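"""Multi-source burned-area reconstruction.

Builds continuous national and regional burned-area series from overlapping,
partially discontinued sources: a national statistical compilation covering
the early decades, state-level agency reports with missing years and a
discontinued category, regional published totals used to back out the
discontinued component by subtraction, and satellite land-cover class tables
covering the recent decades.

The seam rule is fixed: the satellite source is authoritative from the
switch year onward; overlapping historical values are logged, never
averaged.  Negative subtraction residuals are clamped to zero and logged as
diagnostics — burned area cannot be negative, and residuals at the observed
source-agreement level are treated as reporting noise.  Missing years stay
gaps; nothing is interpolated into a balance computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    AnnualSeries,
    BurnedAreaRecord,
    ForestCategory,
    Geography,
    ValidationError,
    fsum_series,
)

__all__ = [
    "ReconstructionResult",
    "SourceSeries",
    "SpliceResult",
    "aggregate_landcover_classes",
    "aggregate_states_to_regions",
    "infer_missing_state_private",
    "moving_average",
    "source_agreement",
    "splice_national",
]


@dataclass(frozen=True)
class SourceSeries:
    """One source's annual burned-area series for one geography."""

    source: str
    geography: Geography
    category_scope: frozenset
    series: AnnualSeries

    def __post_init__(self):
        if not self.category_scope:
            raise ValidationError("category_scope must be non-empty")
        if self.series.unit != "ha":
            raise ValidationError(f"source series must be in ha, got {self.series.unit!r}")


@dataclass
class SpliceResult:
    series: AnnualSeries
    provenance: dict[int, str]
    diagnostics: list[dict] = field(default_factory=list)


@dataclass
class ReconstructionResult:
    """Continuous national series plus regional per-category series.

    ``provenance`` maps each national year to exactly one source tag;
    ``diagnostics`` records every adjustment event (clamped negatives,
    discarded overlaps, excluded-window removals).
    """

    national: AnnualSeries
    regional: dict[str, dict[ForestCategory, AnnualSeries]]
    provenance: dict[int, str]
    diagnostics: list[dict] = field(default_factory=list)

    def regional_total(self, region: str) -> AnnualSeries:
        """Sum of the three categories; a year is defined only if all are."""
        per_cat = self.regional[region]
        series = list(per_cat.values())
        years = set.intersection(*(set(s.values) for s in series))
        all_years = set()
        for s in series:
            all_years |= set(s.values) | s.gaps
        return AnnualSeries(
            "ha",
            {y: fsum_series(s.get(y) for s in series) for y in years},
            {y for y in all_years if y not in years},
        )


def splice_national(
    historical: SourceSeries, satellite: SourceSeries, switch_year: int
) -> SpliceResult:
    """Join a historical and a satellite national series at a switch year.

    The output equals the historical source strictly before ``switch_year``
    and the satellite source from it onward.  The historical source must
    reach ``switch_year - 1`` without a gap at the seam; overlap years
    present in both are resolved in favour of the satellite and logged.
    """
    hist, sat = historical.series, satellite.series
    start = hist.span[0]
    end = sat.span[1]
    missing = [y for y in range(start, switch_year) if y not in hist]
    if missing:
        raise ValidationError(
            f"historical source {historical.source!r} has gaps before the "
            f"seam at {switch_year}: missing years {missing}"
        )
    missing_sat = [y for y in range(switch_year, end + 1) if y not in sat]
    if missing_sat:
        raise ValidationError(
            f"satellite source {satellite.source!r} does not cover "
            f"[{switch_year}, {end}]: missing years {missing_sat}"
        )
    values: dict[int, float] = {}
    provenance: dict[int, str] = {}
    diagnostics: list[dict] = []
    for y in range(start, switch_year):
        values[y] = hist.get(y)
        provenance[y] = historical.source
    for y in range(switch_year, end + 1):
        values[y] = sat.get(y)
        provenance[y] = satellite.source
        if y in hist:
            diagnostics.append(
                {
                    "event": "overlap_discarded",
                    "year": y,
                    "source": historical.source,
                    "discarded_value": hist.get(y),
                    "kept_value": sat.get(y),
                }
            )
    return SpliceResult(AnnualSeries("ha", values), provenance, diagnostics)


def aggregate_states_to_regions(
    records: list[BurnedAreaRecord],
    membership: dict[str, str],
    span: tuple[int, int] | None = None,
) -> dict[str, dict[ForestCategory, AnnualSeries]]:
    """Aggregate state-level records to the four regions, per category.

    Protection status is summed away (protected + unprotected + unspecified).
    Within the span, a (region, category, year) is a gap iff no member state
    reported that category that year; otherwise the value is the sum over
    reporting states.
    """
    for rec in records:
        if rec.geography.level != "state":
            raise ValidationError(f"expected state-level records, got {rec.geography}")
        if rec.geography.code not in membership:
            raise ValidationError(f"state {rec.geography.code!r} not in region membership map")
    if span is None:
        if not records:
            raise ValidationError("no records and no span given")
        years = [r.year for r in records]
        span = (min(years), max(years))
    buckets: dict[tuple[str, ForestCategory, int], list[float]] = {}
    for rec in records:
        region = membership[rec.geography.code]
        buckets.setdefault((region, rec.category, rec.year), []).append(rec.area)
    regions = sorted(set(membership.values()))
    out: dict[str, dict[ForestCategory, AnnualSeries]] = {}
    for region in regions:
        out[region] = {}
        for cat in ForestCategory:
            values = {}
            gaps = set()
            for y in range(span[0], span[1] + 1):
                areas = buckets.get((region, cat, y))
                if areas is None:
                    gaps.add(y)
                else:
                    values[y] = fsum_series(sorted(areas))
            out[region][cat] = AnnualSeries("ha", values, gaps)
    return out


def infer_missing_state_private(
    regional_total: AnnualSeries, covered_components: AnnualSeries
) -> tuple[AnnualSeries, list[dict]]:
    """Back out an unreported component as (published total - covered sum).

    Years defined in both inputs yield ``max(0, total - covered)``; negative
    raw differences are clamped to zero and returned as clamp diagnostics.
    Years missing in either input are gaps.
    """
    if regional_total.unit != covered_components.unit:
        raise ValidationError(
            f"unit mismatch: {regional_total.unit!r} vs {covered_components.unit!r}"
        )
    values: dict[int, float] = {}
    gaps: set[int] = set()
    diagnostics: list[dict] = []
    total_years = set(regional_total.values) | regional_total.gaps
    covered_years = set(covered_components.values) | covered_components.gaps
    for y in total_years | covered_years:
        if y in regional_total and y in covered_components:
            diff = regional_total.get(y) - covered_components.get(y)
            if diff < 0:
                diagnostics.append(
                    {"event": "negative_clamped", "year": y, "raw_difference": diff}
                )
                diff = 0.0
            values[y] = diff
        else:
            gaps.add(y)
    return AnnualSeries(regional_total.unit, values, gaps), diagnostics


def aggregate_landcover_classes(
    class_table: dict[tuple[int, str, str, str], float],
    class_map: dict[str, object],
    excluded_classes: set[str] = frozenset(),
) -> tuple[list[BurnedAreaRecord], list[dict]]:
    """Aggregate satellite land-cover class areas into burned-area records.

    ``class_table`` maps (year, state, class, ownership) to hectares.
    ``class_map`` sends each class either to a :class:`ForestCategory` or to
    the sentinel string ``"forest"``, meaning the category is resolved from
    the ownership column (state_private or federal).  Classes in
    ``excluded_classes`` (e.g. herbaceous, agricultural) never appear in the
    output; their total excluded area is reported.

    Records are summed within (year, state, category, ownership) and tagged
    with source ``"landsat"``.
    """
    excluded_total: dict[str, float] = {}
    buckets: dict[tuple[int, str, ForestCategory, str], list[float]] = {}
    for (year, state, cls, ownership), area in class_table.items():
        if cls in excluded_classes:
            excluded_total[cls] = excluded_total.get(cls, 0.0) + area
            continue
        if cls not in class_map:
            raise ValidationError(
                f"land-cover class {cls!r} neither mapped to a category nor excluded"
            )
        target = class_map[cls]
        if target == "forest":
            category = ForestCategory(ownership)
        else:
            category = ForestCategory(target)
        buckets.setdefault((year, state, category, ownership), []).append(area)
    records = [
        BurnedAreaRecord(
            year=year,
            geography=Geography.state(state),
            category=category,
            protection="unspecified",
            area=fsum_series(sorted(areas)),
            source="landsat",
        )
        for (year, state, category, ownership), areas in sorted(
            buckets.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value, kv[0][3])
        )
    ]
    report = [
        {"event": "class_excluded", "class": cls, "total_area": total}
        for cls, total in sorted(excluded_total.items())
    ]
    return records, report


def moving_average(series: AnnualSeries, window: int = 5) -> AnnualSeries:
    """Centered moving average over available (non-gap) years.

    The window shrinks at the series edges; gap years inside a window are
    simply excluded from the mean.  A year stays a gap only when no year in
    its window is defined.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be an odd integer >= 1, got {window}")
    half = window // 2
    y0, y1 = series.span
    values: dict[int, float] = {}
    gaps: set[int] = set()
    for y in range(y0, y1 + 1):
        if y not in series and y not in series.gaps:
            continue
        window_vals = [
            series.get(w)
            for w in range(max(y0, y - half), min(y1, y + half) + 1)
            if w in series
        ]
        if window_vals:
            values[y] = fsum_series(window_vals) / len(window_vals)
        else:
            gaps.add(y)
    return AnnualSeries(series.unit, values, gaps)


def source_agreement(
    a: AnnualSeries, b: AnnualSeries
) -> tuple[dict[int, float], tuple[float, float]]:
    """Per-year agreement ratio min/max (in %) between two sources.

    Returns the per-year ratios over the overlap plus the (min, max)
    summary.  Two zero reports agree perfectly; a zero against a positive
    report is 0% agreement.  Symmetric in its arguments.
    """
    overlap = sorted(set(a.values) & set(b.values))
    if not overlap:
        raise ValidationError("no overlapping non-gap years between the two series")
    ratios: dict[int, float] = {}
    for y in overlap:
        va, vb = a.get(y), b.get(y)
        lo, hi = min(va, vb), max(va, vb)
        if hi == 0:
            ratios[y] = 100.0
        else:
            ratios[y] = 100.0 * lo / hi
    vals = list(ratios.values())
    return ratios, (min(vals), max(vals))
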