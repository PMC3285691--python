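"""Scenario transforms: odds/reach arithmetic, elasticities, preset fidelity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tobaccosim as ts
from tobaccosim import scenarios
from tobaccosim.scenarios import (apply_price_policy, build_scenario_bundle,
                                  prevalence_reduction_from_price,
                                  transform_quit_rates_or,
                                  transform_start_rates)
from tobaccosim.types import AgeSexTable, ScenarioSpec


def rate_table(value, age_max=50):
    return AgeSexTable.constant(value, age_max)


class TestQuitOddsRatio:
    def test_or_two_full_reach(self):
        q = transform_quit_rates_or(rate_table(0.05), 2.0, 1.0)
        # odds 0.0526316 -> 0.1052632 -> probability 0.0952381
        np.testing.assert_allclose(q.values, 0.0952381, rtol=1e-6)

    def test_or_one_is_identity(self):
        for reach in (0.0, 0.4, 1.0):
            q = transform_quit_rates_or(rate_table(0.07), 1.0, reach)
            np.testing.assert_allclose(q.values, 0.07, atol=1e-15)

    def test_partial_reach_is_mixture(self):
        q = transform_quit_rates_or(rate_table(0.05), 2.0, 0.2)
        np.testing.assert_allclose(q.values, 0.2 * 0.0952381 + 0.8 * 0.05,
                                   rtol=1e-6)

    def test_target_ages_respected(self):
        q = transform_quit_rates_or(rate_table(0.05), 2.0, 1.0,
                                    target_ages=(18, 50))
        assert np.all(q.values[:18] == 0.05)
        assert np.all(q.values[18:] > 0.09)

    def test_probability_one_is_an_error(self):
        t = rate_table(0.05)
        t.values[30, 0] = 1.0
        with pytest.raises(ValueError, match="odds"):
            transform_quit_rates_or(t, 2.0, 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 0.95), st.floats(0.1, 5.0), st.floats(0.0, 1.0))
    def test_bounds_preserved(self, q0, odds_ratio, reach):
        q = transform_quit_rates_or(rate_table(q0), odds_ratio, reach)
        assert np.all((q.values >= 0.0) & (q.values <= 1.0))


class TestStartReduction:
    @pytest.mark.parametrize("s0,red,reach,expected", [
        (0.04, 0.5, 1.0, 0.02),    # maximum school intervention
        (0.04, 0.2, 0.5, 0.036),   # realistic: 20% cut, half reached
        (0.04, 0.0, 1.0, 0.04),
    ])
    def test_mixture_arithmetic(self, s0, red, reach, expected):
        s = transform_start_rates(rate_table(s0), red, reach)
        np.testing.assert_allclose(s.values, expected, atol=1e-15)

    def test_target_ages_respected(self):
        s = transform_start_rates(rate_table(0.04), 0.5, 1.0, target_ages=(10, 18))
        assert np.all(s.values[10:19] == 0.02)
        assert np.all(s.values[19:] == 0.04) and np.all(s.values[:10] == 0.04)


class TestPriceElasticity:
    @pytest.mark.parametrize("price,elasticity,expected", [
        (0.95, -0.7, 0.665), (0.95, -0.4, 0.38),
        (0.20, -0.7, 0.14), (0.20, -0.4, 0.08),
    ])
    def test_worked_examples(self, price, elasticity, expected):
        assert prevalence_reduction_from_price(price, elasticity) == \
            pytest.approx(expected, abs=1e-12)

    def test_reduction_above_one_rejected(self):
        with pytest.raises(ValueError):
            prevalence_reduction_from_price(2.0, -0.7)


class TestPricePolicy:
    def test_prevalence_shift_and_conservation(self, dutch_bundle):
        spec = scenarios.get_preset("table1_max_price")
        out = apply_price_policy(dutch_bundle, spec)
        cur0 = dutch_bundle.smoking.current
        # youth scaled by 1 - 0.665 = 0.335, adults by 1 - 0.38 = 0.62
        np.testing.assert_allclose(out.smoking.current[:21], 0.335 * cur0[:21],
                                   rtol=1e-12)
        np.testing.assert_allclose(out.smoking.current[21:], 0.62 * cur0[21:],
                                   rtol=1e-12)
        # adults: removed mass lands in former_0
        gained = out.smoking.former[21:, :, 0] - dutch_bundle.smoking.former[21:, :, 0]
        np.testing.assert_allclose(gained, 0.38 * cur0[21:], rtol=1e-12)
        # youth: removed mass lands in never
        gained_n = out.smoking.never[:21] - dutch_bundle.smoking.never[:21]
        np.testing.assert_allclose(gained_n, 0.665 * cur0[:21], rtol=1e-12)
        # class sums still exactly one
        np.testing.assert_allclose(out.smoking.as_matrix().sum(axis=2), 1.0,
                                   atol=1e-9)

    def test_zero_price_increase_is_identity(self, dutch_bundle):
        spec = ScenarioSpec(variant="price_policy", price_increase=0.0)
        assert apply_price_policy(dutch_bundle, spec) == dutch_bundle

    def test_restart_multipliers_table_vs_derived(self, dutch_bundle):
        table = apply_price_policy(dutch_bundle,
                                   scenarios.get_preset("table1_max_price"))
        np.testing.assert_allclose(
            table.rates.restart.values, 0.30 * dutch_bundle.rates.restart.values,
            rtol=1e-12)
        derived = apply_price_policy(dutch_bundle, ScenarioSpec(
            variant="price_policy", price_increase=0.95,
            restart_multiplier="derived"))
        np.testing.assert_allclose(
            derived.rates.restart.values,
            (1.0 - 0.665) * dutch_bundle.rates.restart.values, rtol=1e-12)

    def test_adolescent_start_rates_hold_scaled_prevalence(self, dutch_bundle):
        from tobaccosim.lifetable import cohort_prevalence_from_rates
        spec = scenarios.get_preset("table1_max_price")
        out = apply_price_policy(dutch_bundle, spec)
        for si in (0, 1):
            window = np.arange(10, 21)   # ages using the youth elasticity
            rates = out.rates.start.values[window[:-1], si]
            target_ns = 1.0 - 0.335 * dutch_bundle.smoking.current[window, si]
            rebuilt = cohort_prevalence_from_rates(target_ns[0], rates)
            np.testing.assert_allclose(rebuilt, target_ns, atol=1e-12)


class TestBuildScenarioBundle:
    def test_reference_is_identity(self, dutch_bundle):
        assert build_scenario_bundle(dutch_bundle, ts.REFERENCE) == dutch_bundle

    def test_cessation_touches_only_adult_quit_rates(self, dutch_bundle):
        out = build_scenario_bundle(dutch_bundle,
                                    scenarios.get_preset("table1_max_cessation"))
        assert out.smoking == dutch_bundle.smoking
        assert out.rates.start == dutch_bundle.rates.start
        assert out.rates.restart == dutch_bundle.rates.restart
        q0, q1 = dutch_bundle.rates.quit.values, out.rates.quit.values
        np.testing.assert_array_equal(q1[:18], q0[:18])
        assert np.all(q1[18:][q0[18:] > 0] > q0[18:][q0[18:] > 0])

    def test_initiation_touches_only_school_age_start_rates(self, dutch_bundle):
        out = build_scenario_bundle(dutch_bundle,
                                    scenarios.get_preset("table1_max_initiation"))
        assert out.smoking == dutch_bundle.smoking
        assert out.rates.quit == dutch_bundle.rates.quit
        s0, s1 = dutch_bundle.rates.start.values, out.rates.start.values
        np.testing.assert_allclose(s1[10:19], 0.5 * s0[10:19], rtol=1e-12)
        np.testing.assert_array_equal(s1[:10], s0[:10])
        np.testing.assert_array_equal(s1[19:], s0[19:])

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(variant="nonsense")


class TestReachLinearity:
    def test_effect_interpolates_linearly_in_reach(self, dutch_bundle):
        """reach r gives r x (full effect) + (1 - r) x (no effect)."""
        full = build_scenario_bundle(dutch_bundle, ScenarioSpec(
            variant="cessation", quit_or=2.0, reach=1.0, target_ages=(18, 105)))
        half = build_scenario_bundle(dutch_bundle, ScenarioSpec(
            variant="cessation", quit_or=2.0, reach=0.5, target_ages=(18, 105)))
        expected = 0.5 * full.rates.quit.values + 0.5 * dutch_bundle.rates.quit.values
        np.testing.assert_allclose(half.rates.quit.values, expected, atol=1e-15)

    def test_zero_reach_is_reference(self, dutch_bundle):
        for spec in (ScenarioSpec(variant="cessation", quit_or=2.0, reach=0.0),
                     ScenarioSpec(variant="initiation", start_reduction=0.5,
                                  reach=0.0),
                     ScenarioSpec(variant="price_policy", price_increase=0.95,
                                  reach=0.0)):
            assert build_scenario_bundle(dutch_bundle, spec) == dutch_bundle


def test_scenario_ordering_in_smoking_person_years(dutch_bundle, max_runs):
    """Cumulative current-smoker person-years averted over the first 15
    years: population-wide price policy > cessation > initiation."""
    ref = max_runs["reference"]
    averted = {}
    for name in ("table1_max_price", "table1_max_cessation",
                 "table1_max_initiation"):
        run = max_runs[name]
        averted[name] = sum(
            ref.states[i].count[:, :, 1].sum() - run.states[i].count[:, :, 1].sum()
            for i in range(16))
    assert averted["table1_max_price"] > averted["table1_max_cessation"] \
        > averted["table1_max_initiation"] > 0
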