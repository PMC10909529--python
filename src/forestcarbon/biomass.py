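"""Burned-biomass estimation from burned area, fuel loads and combustion completeness.

Burned biomass in year y is

    B(y) = BA(y) * sum_c FL_c(y) * CC_c(y) * carbon_fraction

where BA is burned area (ha), FL_c the fuel load of compartment c
(t DM/ha), CC_c the combustion completeness of compartment c (fraction in
[0, 1]), and carbon_fraction converts dry matter to carbon (default 0.5).
Completeness is applied per compartment and then summed — never as one
aggregate factor — because the compartment resolution is what makes the
severity sub-variants of the sensitivity design well defined.

Fuel loads are anchored to a contemporary field-measured reference period
and carried through time by multiplicative yearly change coefficients from
a fire-enabled vegetation model (consumed here as inputs).  Years before
the first modeled year are filled by constant extrapolation of the first
modeled year's loads and completeness.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .core import AnnualSeries, ForestCategory, Geography, ValidationError, fsum_series

__all__ = [
    "BurnedBiomassSeries",
    "FuelCompartment",
    "FuelProfile",
    "FuelTimeline",
    "OTHER_FOREST_COMPARTMENTS",
    "allocate_fuels",
    "build_fuel_timeline",
    "burned_biomass",
    "extrapolate_pre_span",
    "static_timeline",
    "weighted_mean_timeline",
]


class FuelCompartment(str, Enum):
    """Seven fuel compartments: duff/litter, dead wood by moisture time-lag
    class (1/10/100/1000 hr — finest dries fastest), herbaceous, canopy."""

    DUFF_LITTER = "duff_litter"
    DEAD_1HR = "dead_1hr"
    DEAD_10HR = "dead_10hr"
    DEAD_100HR = "dead_100hr"
    DEAD_1000HR = "dead_1000hr"
    HERB = "herb"
    CANOPY = "canopy"


#: Compartments assumed present in sparse "other forest" (wood/shrub/scrub):
#: duff/litter, fine dead wood (small branches from dead shrubs), and
#: grasses/herbs.  Productive forests carry all seven.
OTHER_FOREST_COMPARTMENTS = frozenset(
    {FuelCompartment.DUFF_LITTER, FuelCompartment.DEAD_1HR, FuelCompartment.HERB}
)


@dataclass(frozen=True)
class FuelProfile:
    """Reference-period mean fuel loads (t DM/ha) per compartment."""

    region: Geography
    category: ForestCategory
    loads: dict
    reference_period: tuple[int, int]

    def __post_init__(self):
        for c, v in self.loads.items():
            if v < 0:
                raise ValidationError(f"fuel load must be non-negative: {c} = {v}")


@dataclass
class FuelTimeline:
    """Per-year fuel loads and combustion completeness for one region.

    ``loads`` and ``completeness`` are year-indexed DataFrames with one
    column per compartment value; completeness entries lie in [0, 1].
    """

    region: Geography
    loads: pd.DataFrame
    completeness: pd.DataFrame

    def __post_init__(self):
        if (self.loads.values < 0).any():
            raise ValidationError("fuel loads must be non-negative")
        cc = self.completeness.values
        if (cc < 0).any() or (cc > 1).any():
            raise ValidationError("combustion completeness must lie in [0, 1]")

    @property
    def span(self) -> tuple[int, int]:
        return int(self.loads.index.min()), int(self.loads.index.max())


@dataclass
class BurnedBiomassSeries:
    """Annual burned biomass in tC, optionally with a per-area companion."""

    geography: Geography
    category: ForestCategory | None
    series: AnnualSeries
    per_area: AnnualSeries | None = None


def allocate_fuels(profile: FuelProfile, category: ForestCategory) -> dict:
    """Filter a fuel profile to the compartments present in a category.

    Productive forests (state & private, federal) keep all seven
    compartments; other forest keeps only duff/litter, 1-hr dead wood and
    herbs.  Absent compartments are removed, not zeroed.
    """
    if category is ForestCategory.OTHER_FOREST:
        return {c: v for c, v in profile.loads.items() if c in OTHER_FOREST_COMPARTMENTS}
    return dict(profile.loads)


def build_fuel_timeline(
    base: FuelProfile,
    coefficients: pd.DataFrame,
    completeness: pd.DataFrame,
    span: tuple[int, int] | None = None,
) -> FuelTimeline:
    """Scale reference-period base loads by yearly change coefficients.

    Coefficients are multiplicative and expressed relative to the reference
    period: the timeline is anchored so that its mean over the reference
    period equals the base load, compartment by compartment.
    """
    if (coefficients.values <= 0).any():
        raise ValidationError("change coefficients must be strictly positive")
    cols = [c for c in coefficients.columns]
    if span is not None:
        coefficients = coefficients.loc[span[0] : span[1]]
        completeness = completeness.loc[span[0] : span[1]]
    ref0, ref1 = base.reference_period
    ref = coefficients.loc[ref0:ref1]
    if ref.empty:
        raise ValidationError(
            f"reference period {base.reference_period} outside coefficient span"
        )
    anchored = coefficients / ref.mean(axis=0)
    loads = pd.DataFrame(index=coefficients.index)
    for c in cols:
        comp = FuelCompartment(c)
        if comp in base.loads:
            loads[c] = anchored[c] * base.loads[comp]
    return FuelTimeline(base.region, loads, completeness.loc[loads.index, loads.columns])


def static_timeline(
    base: FuelProfile, completeness_row: dict, span: tuple[int, int]
) -> FuelTimeline:
    """Constant timeline: reference-period loads and one completeness set
    held fixed over the span (the "static" arm of the sensitivity design)."""
    years = range(span[0], span[1] + 1)
    cols = [c.value for c in base.loads]
    loads = pd.DataFrame(
        {c.value: [base.loads[c]] * len(list(years)) for c in base.loads},
        index=pd.Index(range(span[0], span[1] + 1), name="year"),
        columns=cols,
    )
    cc = pd.DataFrame(
        {
            c.value: [completeness_row[FuelCompartment(c.value)]] * len(loads.index)
            for c in base.loads
        },
        index=loads.index,
        columns=cols,
    )
    return FuelTimeline(base.region, loads, cc)


def extrapolate_pre_span(
    timeline: FuelTimeline, first_modeled_year: int, back_to: int
) -> FuelTimeline:
    """Extend a timeline backwards by holding the first modeled year constant.

    Years [back_to, first_modeled_year - 1] receive the loads and
    completeness of ``first_modeled_year`` unchanged.
    """
    if back_to >= first_modeled_year:
        raise ValidationError(
            f"back_to ({back_to}) must precede first modeled year ({first_modeled_year})"
        )
    if first_modeled_year not in timeline.loads.index:
        raise ValidationError(f"first modeled year {first_modeled_year} not in timeline")
    new_years = list(range(back_to, first_modeled_year))
    pre_loads = pd.DataFrame(
        [timeline.loads.loc[first_modeled_year]] * len(new_years), index=new_years
    )
    pre_cc = pd.DataFrame(
        [timeline.completeness.loc[first_modeled_year]] * len(new_years), index=new_years
    )
    return FuelTimeline(
        timeline.region,
        pd.concat([pre_loads, timeline.loads]).sort_index(),
        pd.concat([pre_cc, timeline.completeness]).sort_index(),
    )


def weighted_mean_timeline(
    timelines: dict[str, FuelTimeline], weights: dict[str, float], geography: Geography
) -> FuelTimeline:
    """Area-weighted mean of regional timelines, for national-scale estimation."""
    total = fsum_series(weights.values())
    if total <= 0:
        raise ValidationError("weights must sum to a positive value")
    regions = sorted(timelines)
    loads = sum(timelines[r].loads * (weights[r] / total) for r in regions)
    cc = sum(timelines[r].completeness * (weights[r] / total) for r in regions)
    return FuelTimeline(geography, loads, cc)


def burned_biomass(
    area: AnnualSeries,
    timeline: FuelTimeline,
    category: ForestCategory | None,
    carbon_fraction: float = 0.5,
    compartments: frozenset | None = None,
) -> BurnedBiomassSeries:
    """Burned biomass B(y) = BA(y) * sum_c FL_c(y) * CC_c(y) * carbon_fraction.

    Gaps in burned area propagate to gaps in burned biomass; years outside
    the timeline span are dropped.  ``compartments``, when given, restricts
    the sum (used by the category allocation rule and the exclude-duff
    sensitivity toggle); by default the allocation for ``category`` applies.
    """
    if area.unit != "ha":
        raise ValidationError(f"burned area must be in ha, got {area.unit!r}")
    if compartments is None:
        if category is ForestCategory.OTHER_FOREST:
            compartments = OTHER_FOREST_COMPARTMENTS
        else:
            compartments = frozenset(FuelCompartment)
    cols = [c.value for c in FuelCompartment if c in compartments and c.value in timeline.loads.columns]
    ty0, ty1 = timeline.span
    values: dict[int, float] = {}
    gaps: set[int] = set()
    for y in range(*_overlap(area.span, (ty0, ty1))):
        if y in area:
            fuel_term = fsum_series(
                float(timeline.loads.at[y, c]) * float(timeline.completeness.at[y, c])
                for c in cols
            )
            values[y] = area.get(y) * fuel_term * carbon_fraction
        elif y in area.gaps:
            gaps.add(y)
    return BurnedBiomassSeries(
        geography=timeline.region, category=category, series=AnnualSeries("tC", values, gaps)
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    if lo > hi:
        raise ValidationError(f"spans {a} and {b} do not overlap")
    return lo, hi + 1
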