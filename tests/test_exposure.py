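"""Deterministic SED engine: routes, aggregation, rescaling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggexpo import exposure
from aggexpo.exposure import (
    AggregateScenario,
    NoExposureError,
    build_aggregate_scenario,
    predict_participant,
    rescale_concentration,
    sccs_aggregate,
    sed_dermal,
    sed_oral_incidental,
)
from aggexpo.study_io import PredictionSet, TableValidationError


class TestDermalRoute:
    def test_body_lotion_hand_calculation(self):
        # 7.82 g/d, leave-on, C = 0.1%, D = 3.7%, 58 kg
        sed = sed_dermal(7.82, 1.0, 0.001, 0.037, 58.0)
        assert sed == pytest.approx(7.82e6 / 58 * 0.001 * 0.037, rel=1e-12)
        assert sed == pytest.approx(4.989, abs=5e-4)

    @given(
        amount=st.floats(0.1, 50.0),
        retention=st.floats(0.01, 1.0),
        conc=st.floats(1e-4, 0.01),
        absorption=st.floats(0.01, 1.0),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_linearity_in_each_factor(self, amount, retention, conc, absorption, scale):
        base = sed_dermal(amount, retention, conc, absorption, 60.0)
        assert sed_dermal(amount * scale, retention, conc, absorption, 60.0) == pytest.approx(base * scale, rel=1e-9)
        if retention * scale <= 1:
            assert sed_dermal(amount, retention * scale, conc, absorption, 60.0) == pytest.approx(base * scale, rel=1e-9)
        if conc * scale < 1:
            assert sed_dermal(amount, retention, conc * scale, absorption, 60.0) == pytest.approx(base * scale, rel=1e-9)
        if absorption * scale <= 1:
            assert sed_dermal(amount, retention, conc, absorption * scale, 60.0) == pytest.approx(base * scale, rel=1e-9)

    def test_doubling_concentration_doubles_dose(self):
        low = sed_dermal(10.0, 1.0, 0.001, 0.037, 60.0)
        high = sed_dermal(10.0, 1.0, 0.002, 0.037, 60.0)
        assert high == pytest.approx(2 * low)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(TableValidationError):
            sed_dermal(-1.0, 1.0, 0.001, 0.037, 60.0)
        with pytest.raises(TableValidationError):
            sed_dermal(1.0, 1.5, 0.001, 0.037, 60.0)
        with pytest.raises(TableValidationError):
            sed_dermal(1.0, 1.0, 0.001, 0.037, 0.0)


class TestOralRoute:
    def test_fraction_of_amount_used(self):
        # 2.75 g/d toothpaste, 5% swallowed, C = 0.3%, full absorption, 58 kg
        sed = sed_oral_incidental(
            0.003, 58.0, amount_g_d=2.75, ingested_fraction=0.05
        )
        assert sed == pytest.approx(0.1375 * 0.003 * 1e6 / 58, rel=1e-12)
        assert sed == pytest.approx(7.112, abs=5e-4)

    def test_fixed_ingested_mass(self):
        sed = sed_oral_incidental(0.003, 58.0, fixed_ingested_g=0.08)
        assert sed == pytest.approx(0.08 * 0.003 * 1e6 / 58, rel=1e-12)
        assert sed == pytest.approx(4.138, abs=5e-4)

    def test_both_or_neither_ingestion_spec_rejected(self):
        with pytest.raises(TableValidationError):
            sed_oral_incidental(
                0.003, 58.0, amount_g_d=2.75, ingested_fraction=0.05,
                fixed_ingested_g=0.08,
            )
        with pytest.raises(TableValidationError):
            sed_oral_incidental(0.003, 58.0, amount_g_d=2.75)


class TestParticipantAggregation:
    def test_single_product_pair_equals_product_sed(self, fixtures):
        # participant 5 uses one MP product (day cream)
        pred = predict_participant(
            fixtures.profiles["5"], fixtures.participants["5"],
            fixtures.ingredients["MP"], fixtures.products, "sccs", "max",
        )
        expected = sed_dermal(1.54, 1.0, 0.004, 0.037, 66.0)
        assert pred.value == pytest.approx(expected, rel=1e-12)

    def test_aggregation_is_sum_of_per_product_seds(self, fixtures):
        # independent hand oracle for participant 1 / MP under one source:
        # (shampoo 10.46 + shower gel 18.67) rinse-off at R=0.01,
        # day cream 1.54 + body lotion 7.82 leave-on at R=1,
        # C=0.4%, D=3.7%, BW 58.
        effective_g = (10.46 + 18.67) * 0.01 + 1.54 + 7.82
        oracle = effective_g * 1e6 / 58 * 0.004 * 0.037
        pred = predict_participant(
            fixtures.profiles["1"], fixtures.participants["1"],
            fixtures.ingredients["MP"], fixtures.products, "sccs", "max",
        )
        assert pred.value == pytest.approx(oracle, rel=1e-12)
        assert pred.value == pytest.approx(24.6275, abs=5e-4)

    def test_triclosan_uses_product_specific_absorption(self, fixtures):
        # participant 5 / TCS: deodorant (D=7.7%) + shower gel (D=7.2%)
        pred = predict_participant(
            fixtures.profiles["5"], fixtures.participants["5"],
            fixtures.ingredients["TCS"], fixtures.products, "sccs", "max",
        )
        oracle = (
            sed_dermal(1.43, 1.0, 0.003, 0.077, 66.0)
            + sed_dermal(18.67, 0.01, 0.003, 0.072, 66.0)
        )
        assert pred.value == pytest.approx(oracle, rel=1e-12)

    def test_toothpaste_goes_through_oral_route(self, fixtures):
        # participant 1 / TCS is toothpaste-only
        pred = predict_participant(
            fixtures.profiles["1"], fixtures.participants["1"],
            fixtures.ingredients["TCS"], fixtures.products, "sccs", "max",
        )
        oracle = sed_oral_incidental(
            0.003, 58.0, amount_g_d=2.75, ingested_fraction=0.05
        )
        assert pred.value == pytest.approx(oracle, rel=1e-12)

    def test_irrelevant_pair_is_explicit_no_exposure(self, fixtures):
        with pytest.raises(NoExposureError):
            predict_participant(
                fixtures.profiles["3"], fixtures.participants["3"],
                fixtures.ingredients["TCS"], fixtures.products, "sccs", "max",
            )


class TestAggregateScenario:
    def test_single_product_basket_equals_dermal_sed(self):
        scenario = AggregateScenario(
            "one", (("body_lotion", 7.82, 1.0),), 0.004, 0.037, 60.0
        )
        assert sccs_aggregate(scenario) == pytest.approx(
            sed_dermal(7.82, 1.0, 0.004, 0.037, 60.0)
        )

    def test_prediction_identical_across_participants(self, fixtures):
        # the default basket ignores individual product use entirely
        ing = fixtures.ingredients["MP"]
        values = {
            sccs_aggregate(
                build_aggregate_scenario(ing, fixtures.config, "max", body_weight_kg=60.0)
            )
            for _ in fixtures.participants
        }
        assert len(values) == 1

    def test_doubling_every_amount_doubles_output(self, fixtures):
        ing = fixtures.ingredients["MP"]
        base = build_aggregate_scenario(ing, fixtures.config, "max", 60.0)
        doubled = AggregateScenario(
            base.label,
            tuple((n, 2 * a, r) for n, a, r in base.product_table),
            base.concentration, base.dermal_d, base.body_weight_kg,
        )
        assert sccs_aggregate(doubled) == pytest.approx(2 * sccs_aggregate(base))

    def test_aggregation_permutation_invariant(self, fixtures):
        ing = fixtures.ingredients["MP"]
        base = build_aggregate_scenario(ing, fixtures.config, "max", 60.0)
        reversed_ = AggregateScenario(
            base.label, tuple(reversed(base.product_table)),
            base.concentration, base.dermal_d, base.body_weight_kg,
        )
        assert sccs_aggregate(reversed_) == pytest.approx(sccs_aggregate(base))

    def test_empty_basket_rejected(self):
        with pytest.raises(TableValidationError):
            AggregateScenario("none", (), 0.004, 0.037, 60.0)


class TestConcentrationRescaling:
    def test_max_to_typical_scenario(self):
        pred = PredictionSet("m", "1", "MP", "point", 12.04, "max")
        rescaled = rescale_concentration(pred, 0.004, 0.001)
        assert rescaled.value == pytest.approx(3.01)

    def test_identity_and_invertibility(self):
        pred = PredictionSet("m", "1", "MP", "point", 5.5, "max")
        assert rescale_concentration(pred, 0.004, 0.004).value == pytest.approx(5.5)
        twice = rescale_concentration(
            rescale_concentration(pred, 0.004, 0.001), 0.001, 0.004
        )
        assert twice.value == pytest.approx(5.5, rel=1e-12)

    def test_rescaling_consistent_with_direct_computation(self, fixtures):
        at_max = predict_participant(
            fixtures.profiles["1"], fixtures.participants["1"],
            fixtures.ingredients["MP"], fixtures.products, "sccs", "max",
        )
        direct = predict_participant(
            fixtures.profiles["1"], fixtures.participants["1"],
            fixtures.ingredients["MP"], fixtures.products, "sccs", 0.001,
        )
        rescaled = rescale_concentration(at_max, 0.004, 0.001)
        assert rescaled.value == pytest.approx(direct.value, rel=1e-12)

    def test_rescales_sample_kind_predictions(self):
        pred = PredictionSet("m", "1", "MP", "samples", (1.0, 2.0, 4.0), "max")
        rescaled = rescale_concentration(pred, 0.004, 0.002)
        assert rescaled.samples == (0.5, 1.0, 2.0)

    def test_zero_source_concentration_rejected(self):
        pred = PredictionSet("m", "1", "MP", "point", 1.0, "max")
        with pytest.raises(TableValidationError):
            rescale_concentration(pred, 0.0, 0.001)


def test_consexpo_toothpaste_uses_fixed_ingested_mass(fixtures):
    sed = exposure.product_sed(
        fixtures.products["toothpaste"], fixtures.ingredients["TCS"],
        "consexpo", 0.003, 58.0,
    )
    assert sed == pytest.approx(0.08 * 0.003 * 1e6 / 58, rel=1e-12)
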