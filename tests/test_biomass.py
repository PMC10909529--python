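import math
import random

import numpy as np
import pandas as pd
import pytest

from forestcarbon import (
    AnnualSeries,
    ForestCategory,
    FuelCompartment,
    FuelProfile,
    FuelTimeline,
    Geography,
    allocate_fuels,
    build_fuel_timeline,
    burned_biomass,
    extrapolate_pre_span,
)
from forestcarbon.biomass import OTHER_FOREST_COMPARTMENTS
from forestcarbon.core import ValidationError

C = FuelCompartment
SE = Geography.region("SE")
COLS = [c.value for c in C]


def _profile(loads=None, ref=(2003, 2015)):
    loads = loads or {C.DUFF_LITTER: 5.0, C.DEAD_1HR: 1.0, C.HERB: 0.5, C.CANOPY: 20.0}
    return FuelProfile(SE, ForestCategory.STATE_PRIVATE, loads, ref)


def _frames(span, loads_fn, cc_fn):
    years = list(range(span[0], span[1] + 1))
    loads = pd.DataFrame({c: [loads_fn(y, c) for y in years] for c in COLS}, index=years)
    cc = pd.DataFrame({c: [cc_fn(y, c) for y in years] for c in COLS}, index=years)
    return loads, cc


class TestAllocation:
    def test_other_forest_keeps_surface_and_herb_fuels_only(self):
        out = allocate_fuels(_profile(), ForestCategory.OTHER_FOREST)
        assert out == {C.DUFF_LITTER: 5.0, C.DEAD_1HR: 1.0, C.HERB: 0.5}

    def test_productive_forest_keeps_all_compartments(self):
        p = _profile()
        assert allocate_fuels(p, ForestCategory.FEDERAL) == p.loads
        assert allocate_fuels(p, ForestCategory.STATE_PRIVATE) == p.loads

    def test_allocation_only_removes_mass(self):
        p = _profile()
        assert sum(allocate_fuels(p, ForestCategory.OTHER_FOREST).values()) <= sum(
            p.loads.values()
        )


class TestFuelTimeline:
    def test_identity_coefficients_reproduce_base(self):
        p = FuelProfile(SE, ForestCategory.FEDERAL, {c: 2.0 for c in C}, (2003, 2015))
        loads, cc = _frames((2000, 2017), lambda y, c: 1.0, lambda y, c: 0.5)
        tl = build_fuel_timeline(p, loads, cc)
        assert np.allclose(tl.loads.values, 2.0)

    def test_coefficients_scale_linearly(self):
        p = FuelProfile(SE, ForestCategory.FEDERAL, {c: 2.0 for c in C}, (2003, 2015))
        coeff, cc = _frames((2003, 2015), lambda y, c: 1.1 if y == 2010 else 1.0, lambda y, c: 0.5)
        # anchoring rescales by the reference mean of the coefficients
        tl = build_fuel_timeline(p, coeff, cc)
        ref_mean = coeff.loc[2003:2015].mean()
        assert np.allclose(tl.loads.loc[2010], 2.0 * 1.1 / ref_mean)

    def test_reference_period_mean_is_anchored_to_base(self):
        rng = np.random.default_rng(5)
        p = FuelProfile(SE, ForestCategory.FEDERAL, {c: 3.7 for c in C}, (2003, 2015))
        years = list(range(1941, 2018))
        coeff = pd.DataFrame(np.exp(0.3 * rng.standard_normal((len(years), 7))),
                             index=years, columns=COLS)
        cc = pd.DataFrame(0.5, index=years, columns=COLS)
        tl = build_fuel_timeline(p, coeff, cc)
        ref_mean = tl.loads.loc[2003:2015].mean()
        assert np.allclose(ref_mean.values, 3.7, atol=1e-9)

    def test_nonpositive_coefficient_rejected(self):
        p = _profile()
        coeff, cc = _frames((2003, 2015), lambda y, c: -1.0, lambda y, c: 0.5)
        with pytest.raises(ValidationError):
            build_fuel_timeline(p, coeff, cc)

    def test_completeness_outside_unit_interval_rejected(self):
        loads, cc = _frames((2000, 2005), lambda y, c: 1.0, lambda y, c: 1.5)
        with pytest.raises(ValidationError):
            FuelTimeline(SE, loads, cc)


class TestExtrapolation:
    def _timeline(self):
        loads, cc = _frames((1941, 1950), lambda y, c: float(y - 1940), lambda y, c: 0.4)
        return FuelTimeline(SE, loads, cc)

    def test_back_fill_is_constant_at_first_modeled_year(self):
        out = extrapolate_pre_span(self._timeline(), 1941, 1926)
        for y in range(1926, 1941):
            assert np.allclose(out.loads.loc[y], out.loads.loc[1941])
            assert np.allclose(out.completeness.loc[y], out.completeness.loc[1941])
        assert out.loads.loc[1926:1940].std().max() == 0.0

    def test_minimal_single_year_extension(self):
        out = extrapolate_pre_span(self._timeline(), 1941, 1940)
        assert out.span == (1940, 1950)

    def test_backwards_range_rejected(self):
        with pytest.raises(ValidationError):
            extrapolate_pre_span(self._timeline(), 1941, 1941)


class TestBurnedBiomass:
    def test_single_compartment_arithmetic(self):
        p = FuelProfile(SE, ForestCategory.FEDERAL, {C.DUFF_LITTER: 10.0}, (2000, 2000))
        loads = pd.DataFrame({C.DUFF_LITTER.value: [10.0]}, index=[2000])
        cc = pd.DataFrame({C.DUFF_LITTER.value: [0.3]}, index=[2000])
        tl = FuelTimeline(SE, loads, cc)
        area = AnnualSeries("ha", {2000: 1.0})
        out = burned_biomass(area, tl, ForestCategory.FEDERAL, carbon_fraction=0.5)
        assert out.series.get(2000) == pytest.approx(1.5)

    def test_zero_area_gives_zero_biomass(self):
        loads, cc = _frames((2000, 2005), lambda y, c: 10.0, lambda y, c: 0.9)
        tl = FuelTimeline(SE, loads, cc)
        out = burned_biomass(AnnualSeries("ha", {y: 0.0 for y in range(2000, 2006)}), tl,
                             ForestCategory.FEDERAL)
        assert all(v == 0.0 for v in out.series.values.values())

    def _random_inputs(self, seed):
        rng = random.Random(seed)
        span = (1980, 2009)
        loads, cc = _frames(
            span, lambda y, c: rng.uniform(0, 30), lambda y, c: rng.uniform(0, 1)
        )
        values = {y: rng.uniform(0, 1e6) for y in range(span[0], span[1] + 1)
                  if rng.random() > 0.1}
        gaps = set(range(span[0], span[1] + 1)) - set(values)
        return AnnualSeries("ha", values, gaps), FuelTimeline(SE, loads, cc)

    def test_matches_per_compartment_summation_oracle(self):
        for seed in range(5):
            area, tl = self._random_inputs(seed)
            out = burned_biomass(area, tl, ForestCategory.FEDERAL, carbon_fraction=0.5)
            for y in out.series.years:
                expected = 0.0
                for c in COLS:
                    expected += float(tl.loads.at[y, c]) * float(tl.completeness.at[y, c])
                expected *= area.get(y) * 0.5
                assert abs(out.series.get(y) - expected) <= 1e-12 * max(1.0, abs(expected))

    def test_gaps_propagate(self):
        area, tl = self._random_inputs(1)
        out = burned_biomass(area, tl, ForestCategory.FEDERAL)
        assert area.gaps <= out.series.gaps | set(out.series.values)
        assert all(y in out.series.gaps for y in area.gaps)

    def test_monotone_in_area_loads_and_completeness(self):
        area, tl = self._random_inputs(2)
        base = burned_biomass(area, tl, ForestCategory.FEDERAL).series
        bigger_area = area.map_values(lambda v: v * 1.07)
        assert all(
            burned_biomass(bigger_area, tl, ForestCategory.FEDERAL).series.get(y) >= base.get(y)
            for y in base.years
        )
        for col in (C.DUFF_LITTER.value, C.CANOPY.value):
            loads2 = tl.loads.copy()
            loads2[col] *= 1.5
            up = burned_biomass(area, FuelTimeline(SE, loads2, tl.completeness),
                                ForestCategory.FEDERAL).series
            assert all(up.get(y) >= base.get(y) for y in base.years)
            cc2 = tl.completeness.copy()
            cc2[col] = (cc2[col] * 1.1).clip(upper=1.0)
            up = burned_biomass(area, FuelTimeline(SE, tl.loads, cc2),
                                ForestCategory.FEDERAL).series
            assert all(up.get(y) >= base.get(y) for y in base.years)

    def test_other_forest_bounded_by_productive(self):
        area, tl = self._random_inputs(3)
        other = burned_biomass(area, tl, ForestCategory.OTHER_FOREST).series
        productive = burned_biomass(area, tl, ForestCategory.FEDERAL).series
        assert all(other.get(y) <= productive.get(y) for y in other.years)

    def test_doubling_loads_doubles_biomass_exactly(self):
        area, tl = self._random_inputs(4)
        base = burned_biomass(area, tl, ForestCategory.FEDERAL).series
        doubled = burned_biomass(
            area, FuelTimeline(SE, tl.loads * 2.0, tl.completeness), ForestCategory.FEDERAL
        ).series
        assert all(doubled.get(y) == 2.0 * base.get(y) for y in base.years)

    def test_completeness_bound(self):
        area, tl = self._random_inputs(5)
        out = burned_biomass(area, tl, ForestCategory.FEDERAL, carbon_fraction=0.5).series
        for y in out.years:
            cap = area.get(y) * float(tl.loads.loc[y].sum()) * 0.5
            assert out.get(y) <= cap * (1 + 1e-12)
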