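import pytest

from forestcarbon import (
    AnnualSeries,
    ExpansionFactors,
    Geography,
    enumerate_variants,
    envelope,
    range_summary,
    run_variant,
)
from forestcarbon.balance import ProductRatios
from forestcarbon.core import REGION_CODES, ValidationError
from forestcarbon.sensitivity import (
    CC_MODES,
    SensitivityInputs,
    VariantSpec,
    harvest_envelope,
)

REGIONS = [Geography.region(r) for r in REGION_CODES]


class TestEnumeration:
    def test_four_regions_yield_48_variants(self):
        assert len(enumerate_variants(REGIONS)) == 48

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_twelve_variants_per_region(self, n):
        assert len(enumerate_variants(REGIONS[:n])) == 12 * n

    def test_output_has_no_duplicates(self):
        specs = enumerate_variants(REGIONS)
        assert len(set(specs)) == len(specs)

    def test_duplicate_region_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_variants([REGIONS[0], REGIONS[0]])

    def test_enumeration_order_is_deterministic(self):
        assert enumerate_variants(REGIONS) == enumerate_variants(REGIONS)


def _inputs(complete_sources, **overrides):
    cfg = complete_sources.config
    kwargs = dict(
        field_profiles=complete_sources.field_profiles,
        modeled_profiles=complete_sources.modeled_profiles,
        coefficients=complete_sources.coefficients,
        modeled_completeness=complete_sources.modeled_completeness,
        severity_completeness=complete_sources.severity,
        burned_area=None,
        span=(cfg.modeled_start, cfg.span[1]),
        carbon_fraction=cfg.carbon_fraction,
    )
    kwargs.update(overrides)
    return kwargs


@pytest.fixture(scope="module")
def sens_inputs(complete_world, complete_result, complete_sources):
    recon = complete_result.reconstruction
    return SensitivityInputs(
        **_inputs(
            complete_sources,
            burned_area={r: recon.regional[r] for r in complete_sources.config.regions},
        )
    )


class TestRunVariant:
    def test_static_equals_dynamic_with_identity_coefficients(self, sens_inputs):
        import pandas as pd

        coeff = {
            r: df * 0.0 + 1.0 for r, df in sens_inputs.coefficients.items()
        }
        modified = SensitivityInputs(
            field_profiles=sens_inputs.field_profiles,
            modeled_profiles=sens_inputs.modeled_profiles,
            coefficients=coeff,
            modeled_completeness=sens_inputs.modeled_completeness,
            severity_completeness=sens_inputs.severity_completeness,
            burned_area=sens_inputs.burned_area,
            span=sens_inputs.span,
            carbon_fraction=sens_inputs.carbon_fraction,
        )
        static = run_variant(
            VariantSpec("field_measured", "static", "moderate", REGIONS[1]), modified
        ).series
        dynamic = run_variant(
            VariantSpec("field_measured", "dynamic", "moderate", REGIONS[1]), modified
        ).series
        for y in static.years:
            assert static.get(y) == pytest.approx(dynamic.get(y), rel=1e-12)

    def test_identical_fuel_tables_make_source_irrelevant(self, sens_inputs):
        same = SensitivityInputs(
            field_profiles=sens_inputs.field_profiles,
            modeled_profiles=sens_inputs.field_profiles,
            coefficients=sens_inputs.coefficients,
            modeled_completeness=sens_inputs.modeled_completeness,
            severity_completeness=sens_inputs.severity_completeness,
            burned_area=sens_inputs.burned_area,
            span=sens_inputs.span,
            carbon_fraction=sens_inputs.carbon_fraction,
        )
        a = run_variant(VariantSpec("field_measured", "static", "low", REGIONS[0]), same).series
        b = run_variant(VariantSpec("modeled", "static", "low", REGIONS[0]), same).series
        assert a == b

    def test_severity_ordering_pointwise(self, sens_inputs):
        for src in ("field_measured", "modeled"):
            for dyn in ("static", "dynamic"):
                for region in REGIONS:
                    runs = {
                        cc: run_variant(VariantSpec(src, dyn, cc, region), sens_inputs).series
                        for cc in CC_MODES
                    }
                    for y in runs["low"].years:
                        assert runs["low"].get(y) <= runs["moderate"].get(y) <= runs["high"].get(y)

    def test_missing_severity_table_is_an_error(self, sens_inputs):
        broken = SensitivityInputs(
            field_profiles=sens_inputs.field_profiles,
            modeled_profiles=sens_inputs.modeled_profiles,
            coefficients=sens_inputs.coefficients,
            modeled_completeness=sens_inputs.modeled_completeness,
            severity_completeness={"low": {}, "moderate": {}, "high": {}},
            burned_area=sens_inputs.burned_area,
            span=sens_inputs.span,
        )
        with pytest.raises(ValidationError):
            run_variant(VariantSpec("field_measured", "static", "low", REGIONS[0]), broken)

    def test_exclude_duff_reduces_estimate(self, sens_inputs):
        spec = VariantSpec("field_measured", "static", "moderate", REGIONS[1])
        full = run_variant(spec, sens_inputs).series
        trimmed = run_variant(spec, sens_inputs, exclude_duff=True).series
        assert all(trimmed.get(y) <= full.get(y) for y in full.years)
        assert any(trimmed.get(y) < full.get(y) for y in full.years)


class TestEnvelope:
    def _const(self, v, years=range(2000, 2005)):
        return AnnualSeries("tC", {y: float(v) for y in years})

    def test_pointwise_min_max(self):
        env = envelope([self._const(1), self._const(3)], self._const(2))
        assert all(env.low.get(y) == 1.0 and env.high.get(y) == 3.0 for y in env.low.years)

    def test_degenerate_duplicate_variant(self):
        env = envelope([self._const(2), self._const(2)], self._const(2))
        assert env.low == env.high

    def test_central_not_clipped(self):
        env = envelope([self._const(1), self._const(3)], self._const(10))
        assert env.central.get(2000) == 10.0

    def test_empty_variant_list_rejected(self):
        with pytest.raises(ValidationError):
            envelope([], self._const(1))

    def test_envelope_contains_every_variant(self, complete_result):
        sens = complete_result.sensitivity
        env = sens.fire_envelope
        by_cell = {}
        for spec, series in sens.variants.items():
            by_cell.setdefault((spec.fuel_source, spec.fuel_dynamics, spec.cc_mode), []).append(
                series
            )
        for cell in by_cell.values():
            years = set.intersection(*(set(s.values) for s in cell)) & set(env.low.values)
            for y in years:
                total = sum(s.get(y) for s in cell) * 1e-6  # TgC
                assert env.low.get(y) - 1e-9 <= total <= env.high.get(y) + 1e-9


class TestRangeSummary:
    def _env(self, central, low, high):
        from forestcarbon.sensitivity import Envelope

        years = range(2000, 2010)
        mk = lambda v: AnnualSeries("TgC/yr", {y: float(v) for y in years})
        return Envelope(central=mk(central), low=mk(low), high=mk(high), component="fire")

    def test_constant_deviations(self):
        s = range_summary(self._env(10, 8, 14))
        assert (s.mean_plus, s.mean_minus) == (4.0, -2.0)
        assert (s.max_plus, s.min_minus) == (4.0, -2.0)

    def test_degenerate_envelope(self):
        s = range_summary(self._env(10, 10, 10))
        assert s.mean_plus == s.mean_minus == 0.0

    def test_matches_brute_force_oracle(self, complete_result):
        env = complete_result.sensitivity.fire_envelope
        got = range_summary(env)
        years = sorted(set(env.central.values) & set(env.low.values))
        plus = [env.high.get(y) - env.central.get(y) for y in years]
        minus = [env.low.get(y) - env.central.get(y) for y in years]
        assert abs(got.mean_plus - sum(plus) / len(plus)) < 1e-12 * max(1, abs(got.mean_plus))
        assert abs(got.mean_minus - sum(minus) / len(minus)) < 1e-12 * max(1, abs(got.mean_minus))
        assert got.max_plus == max(plus) and got.min_minus == min(minus)


class TestHarvestEnvelope:
    def test_factor_ordering_spans_central(self):
        stem = AnnualSeries("tC/yr", {y: 100.0 + y % 7 for y in range(1950, 2000)})
        central = ExpansionFactors(ProductRatios(0.12, 0.25, 0.26), ProductRatios(0.11, 0.2, 0.24))
        mini = ExpansionFactors(ProductRatios(0.08, 0.15, 0.18), ProductRatios(0.07, 0.12, 0.16))
        maxi = ExpansionFactors(ProductRatios(0.2, 0.35, 0.36), ProductRatios(0.18, 0.3, 0.34))
        env = harvest_envelope(stem, central, mini, maxi, 0.4, Geography.national())
        for y in env.central.years:
            assert env.low.get(y) <= env.central.get(y) <= env.high.get(y)
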