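import math
import random

import pytest

from forestcarbon import (
    AnnualSeries,
    BurnedAreaRecord,
    ForestCategory,
    Geography,
    SourceSeries,
    aggregate_landcover_classes,
    aggregate_states_to_regions,
    infer_missing_state_private,
    moving_average,
    source_agreement,
    splice_national,
)
from forestcarbon.core import ValidationError

ALL = frozenset(ForestCategory)


def _src(source, values, geography=None):
    return SourceSeries(
        source=source,
        geography=geography or Geography.national(),
        category_scope=ALL,
        series=AnnualSeries("ha", values),
    )


class TestSpliceNational:
    def test_seam_definition(self):
        out = splice_national(_src("census", {1984: 5.0}), _src("landsat", {1985: 1.0}), 1985)
        assert out.series.values == {1984: 5.0, 1985: 1.0}
        assert out.provenance == {1984: "census", 1985: "landsat"}

    def test_overlap_resolved_to_satellite_and_logged(self):
        out = splice_national(
            _src("census", {1984: 5.0, 1985: 4.0}), _src("landsat", {1985: 1.0}), 1985
        )
        assert out.series.get(1985) == 1.0
        assert out.diagnostics[0]["event"] == "overlap_discarded"
        assert out.diagnostics[0]["discarded_value"] == 4.0

    def test_gap_at_seam_lists_missing_years(self):
        with pytest.raises(ValidationError, match="1983"):
            splice_national(_src("census", {1982: 5.0}), _src("landsat", {1985: 1.0}), 1985)

    def test_provenance_covers_every_year_exactly_once(self):
        hist = _src("census", {y: float(y) for y in range(1926, 1985)})
        sat = _src("landsat", {y: 1.0 for y in range(1985, 2018)})
        out = splice_national(hist, sat, 1985)
        assert sorted(out.provenance) == list(range(1926, 2018))
        assert all(
            (tag == "census") == (y < 1985) for y, tag in out.provenance.items()
        )


def _state_rec(year, state, cat, area):
    return BurnedAreaRecord(year, Geography.state(state), cat, "unspecified", area, "usfs")


MEMBERSHIP = {"GA": "SE", "FL": "SE", "MT": "RM"}


class TestStateAggregation:
    def test_states_sum_within_region(self):
        recs = [
            _state_rec(1950, "GA", ForestCategory.FEDERAL, 3.0),
            _state_rec(1950, "FL", ForestCategory.FEDERAL, 4.0),
        ]
        out = aggregate_states_to_regions(recs, MEMBERSHIP, span=(1950, 1950))
        assert out["SE"][ForestCategory.FEDERAL].get(1950) == 7.0

    def test_year_with_no_reporting_state_is_gap(self):
        recs = [_state_rec(1950, "GA", ForestCategory.FEDERAL, 3.0)]
        out = aggregate_states_to_regions(recs, MEMBERSHIP, span=(1950, 1967))
        assert 1967 in out["SE"][ForestCategory.FEDERAL].gaps

    def test_record_order_is_irrelevant(self):
        recs = [
            _state_rec(1950 + i % 3, s, c, float(i + 1) * 1.37)
            for i, (s, c) in enumerate(
                [(s, c) for s in MEMBERSHIP for c in ForestCategory] * 3
            )
        ]
        shuffled = recs[:]
        random.Random(7).shuffle(shuffled)
        a = aggregate_states_to_regions(recs, MEMBERSHIP, span=(1950, 1952))
        b = aggregate_states_to_regions(shuffled, MEMBERSHIP, span=(1950, 1952))
        for r in a:
            for c in ForestCategory:
                assert a[r][c] == b[r][c]

    def test_unmapped_state_is_an_error(self):
        with pytest.raises(ValidationError, match="CA"):
            aggregate_states_to_regions(
                [_state_rec(1950, "CA", ForestCategory.FEDERAL, 1.0)], MEMBERSHIP
            )


class TestStatePrivateInference:
    def test_subtraction(self):
        total = AnnualSeries("ha", {1965: 100.0})
        covered = AnnualSeries("ha", {1965: 60.0})
        inferred, diags = infer_missing_state_private(total, covered)
        assert inferred.get(1965) == 40.0
        assert diags == []

    def test_negative_difference_clamped_and_logged(self):
        inferred, diags = infer_missing_state_private(
            AnnualSeries("ha", {1965: 50.0}), AnnualSeries("ha", {1965: 55.0})
        )
        assert inferred.get(1965) == 0.0
        assert diags[0]["event"] == "negative_clamped"
        assert diags[0]["raw_difference"] == pytest.approx(-5.0)

    def test_missing_years_stay_gaps(self):
        inferred, _ = infer_missing_state_private(
            AnnualSeries("ha", {1965: 50.0}, {1966}), AnnualSeries("ha", {1966: 10.0})
        )
        assert inferred.gaps == {1965, 1966}

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            infer_missing_state_private(
                AnnualSeries("ha", {1965: 1.0}), AnnualSeries("acre", {1965: 1.0})
            )

    def test_output_never_negative(self):
        rng = random.Random(3)
        total = AnnualSeries("ha", {y: rng.uniform(0, 100) for y in range(1950, 1980)})
        covered = AnnualSeries("ha", {y: rng.uniform(0, 120) for y in range(1950, 1980)})
        inferred, _ = infer_missing_state_private(total, covered)
        assert all(v >= 0 for v in inferred.values.values())


class TestLandcoverAggregation:
    CLASS_MAP = {"deciduous": "forest", "evergreen": "forest", "mixed": "forest",
                 "shrub_scrub": ForestCategory.OTHER_FOREST}

    def test_forest_classes_sum_into_one_record(self):
        table = {
            (2000, "GA", "deciduous", "state_private"): 2.0,
            (2000, "GA", "evergreen", "state_private"): 3.0,
            (2000, "GA", "mixed", "state_private"): 1.0,
        }
        records, _ = aggregate_landcover_classes(table, self.CLASS_MAP)
        assert len(records) == 1
        assert records[0].area == 6.0
        assert records[0].category is ForestCategory.STATE_PRIVATE

    def test_shrubland_maps_to_other_forest(self):
        records, _ = aggregate_landcover_classes(
            {(2000, "GA", "shrub_scrub", "aggregated"): 4.0}, self.CLASS_MAP
        )
        assert records[0].category is ForestCategory.OTHER_FOREST
        assert records[0].area == 4.0

    def test_excluded_class_reported_never_emitted(self):
        table = {
            (2000, "GA", "herbaceous", "aggregated"): 9.0,
            (2000, "GA", "deciduous", "federal"): 1.0,
        }
        records, report = aggregate_landcover_classes(
            table, self.CLASS_MAP, excluded_classes={"herbaceous"}
        )
        assert all(r.category is not None for r in records) and len(records) == 1
        assert report == [{"event": "class_excluded", "class": "herbaceous", "total_area": 9.0}]

    def test_unmapped_class_is_an_error(self):
        with pytest.raises(ValidationError, match="wetland"):
            aggregate_landcover_classes({(2000, "GA", "wetland", "federal"): 1.0}, self.CLASS_MAP)


def _brute_moving_average(series, window):
    half = window // 2
    y0, y1 = series.span
    out = {}
    for y in range(y0, y1 + 1):
        if y not in series and y not in series.gaps:
            continue
        vals = [series.get(w) for w in range(y - half, y + half + 1)
                if y0 <= w <= y1 and w in series]
        if vals:
            out[y] = sum(vals) / len(vals)
    return out


class TestMovingAverage:
    def test_constant_series_is_fixed_point(self):
        s = AnnualSeries("ha", {y: 7.0 for y in range(1950, 1970)})
        assert moving_average(s, 5).values == pytest.approx(s.values)

    def test_symmetric_window_mean(self):
        s = AnnualSeries("ha", {y: float(y) for y in range(1, 6)})
        assert moving_average(s, 5).get(3) == pytest.approx(3.0)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(11)
        for trial in range(10):
            values = {y: rng.uniform(0, 1e6) for y in range(1950, 2000)
                      if rng.random() > 0.1}
            gaps = set(range(1950, 2000)) - set(values)
            s = AnnualSeries("ha", values, gaps)
            for window in (1, 3, 5, 7):
                got = moving_average(s, window)
                expected = _brute_moving_average(s, window)
                assert set(got.values) == set(expected)
                for y, v in expected.items():
                    assert abs(got.get(y) - v) < 1e-12 * max(1.0, abs(v))

    def test_gap_survives_only_if_whole_window_is_gap(self):
        s = AnnualSeries("ha", {1950: 1.0, 1952: 3.0}, {1951, 1955})
        out = moving_average(s, 3)
        assert out.get(1951) == pytest.approx(2.0)  # neighbours defined
        assert 1955 in out.gaps  # isolated gap, window all-gap

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            moving_average(AnnualSeries("ha", {1950: 1.0}), 4)


class TestSourceAgreement:
    def test_identical_series_agree_fully(self):
        s = AnnualSeries("ha", {y: float(y) for y in range(1950, 1960)})
        ratios, (lo, hi) = source_agreement(s, s)
        assert lo == hi == 100.0
        assert all(v == 100.0 for v in ratios.values())

    def test_ratio_definition_and_symmetry(self):
        a = AnnualSeries("ha", {1975: 96.0})
        b = AnnualSeries("ha", {1975: 100.0})
        r_ab, _ = source_agreement(a, b)
        r_ba, _ = source_agreement(b, a)
        assert r_ab[1975] == pytest.approx(96.0)
        assert r_ab == r_ba

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValidationError):
            source_agreement(AnnualSeries("ha", {1950: 1.0}), AnnualSeries("ha", {1960: 1.0}))
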