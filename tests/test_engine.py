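"""Engine unit tests: calibration algebra, step mechanics, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tobaccosim as ts
from tobaccosim import engine
from tobaccosim.engine import (Calibration, InfeasibleInputError,
                               calibrate_class_specific_incidence,
                               derive_other_cause_mortality,
                               derive_state_specific_mortality,
                               run_projection, step_year)
from tobaccosim.types import CURRENT, FORMER0, NEVER


# ---------------------------------------------------------------------------
# incidence calibration
# ---------------------------------------------------------------------------

class TestIncidenceCalibration:
    def test_hand_algebra_example(self):
        # shares (0.5, 0.3, 0.2), rr (1, 10, 4): denom = 0.5 + 3 + 0.8 = 4.3
        i = calibrate_class_specific_incidence(
            0.001, [0.5, 0.3, 0.2], [1.0, 10.0, 4.0])
        assert i[0] == pytest.approx(0.001 / 4.3, rel=1e-12)
        assert i[1] == pytest.approx(0.01 / 4.3, rel=1e-12)
        # share-weighted mean reproduces the population rate exactly
        assert np.dot([0.5, 0.3, 0.2], i) == pytest.approx(0.001, rel=1e-14)

    def test_all_rr_one_returns_population_rate(self):
        i = calibrate_class_specific_incidence(0.02, [0.1, 0.6, 0.3], [1, 1, 1])
        np.testing.assert_allclose(i, 0.02)

    def test_single_class_normalization(self):
        i = calibrate_class_specific_incidence(0.005, [0.0, 1.0, 0.0], [1, 10, 4])
        assert i[1] == pytest.approx(0.005)
        assert i[0] == pytest.approx(0.0005)

    def test_degenerate_shares_raise(self):
        with pytest.raises(InfeasibleInputError):
            calibrate_class_specific_incidence(0.01, [0.0, 0.0], [0.0, 5.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
           st.lists(st.floats(0.1, 20.0), min_size=6, max_size=6),
           st.floats(1e-6, 0.5))
    def test_weighted_mean_contract(self, raw_shares, rr, i_pop):
        shares = np.asarray(raw_shares) / np.sum(raw_shares)
        rr = np.asarray(rr[:len(shares)])
        i = calibrate_class_specific_incidence(i_pop, shares, rr)
        assert np.dot(shares, i) == pytest.approx(i_pop, rel=1e-12)


# ---------------------------------------------------------------------------
# mortality decomposition
# ---------------------------------------------------------------------------

class TestMortalityDecomposition:
    def test_additive_definition(self):
        assert derive_other_cause_mortality(0.010, 0.004) == pytest.approx(0.006)
        assert derive_other_cause_mortality(0.010, 0.0) == pytest.approx(0.010)

    def test_disease_mortality_above_total_raises(self):
        with pytest.raises(InfeasibleInputError):
            derive_other_cause_mortality(0.01, 0.02)

    def test_two_class_hand_example(self):
        # shares (.5, .5), rr (1, 3), m = 0.02: M = (0.01, 0.03)
        total, other = derive_state_specific_mortality(
            0.02, [1.0, 3.0], [0.5, 0.5], [0.0, 0.0])
        np.testing.assert_allclose(total, [0.01, 0.03])
        np.testing.assert_allclose(other, total)
        assert np.dot([0.5, 0.5], total) == pytest.approx(0.02, abs=1e-14)

    def test_rr_one_gives_m_total_everywhere(self):
        total, other = derive_state_specific_mortality(
            0.015, [1.0, 1.0, 1.0], [0.2, 0.5, 0.3], [0.0, 0.0, 0.0])
        np.testing.assert_allclose(total, 0.015)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           st.lists(st.floats(0.5, 5.0), min_size=3, max_size=3),
           st.floats(1e-5, 0.3))
    def test_conservation_contract(self, raw_shares, rr_tail, m):
        shares = np.asarray(raw_shares) / np.sum(raw_shares)
        rr = np.concatenate([[1.0], np.asarray(rr_tail)[:2]])
        total, _ = derive_state_specific_mortality(m, rr, shares,
                                                   np.zeros(3))
        assert abs(np.dot(shares, total) - m) < 1e-14
        assert total[1] / total[0] == pytest.approx(rr[1], rel=1e-12)


# ---------------------------------------------------------------------------
# annual step and full projections
# ---------------------------------------------------------------------------

def _zeroed(bundle):
    """Copy of a bundle with all transitions, incidence and mortality 0."""
    b = bundle.copy()
    for t in (b.rates.start, b.rates.quit, b.rates.restart, b.mortality.m_total):
        t.values[:] = 0.0
    b.mortality.rr_allcause_current[:] = 1.0
    b.mortality.rr_allcause_former[:] = 1.0
    for d in b.diseases:
        d.incidence.values[:] = 0.0
        d.excess_mortality.values[:] = 0.0
    return b


class TestStepYear:
    def test_zero_rates_age_shift_plus_newborns(self, fixture_bundle):
        b = _zeroed(fixture_bundle)
        calib = Calibration.from_bundle(b)
        state = engine.initial_state(b, b, calib)
        nxt, deaths, exits = step_year(state, b, calib)
        assert deaths.sum() == 0.0
        # aggregated class masses shift by one year of age (the
        # time-since-quit clock still advances within the former block)
        old = np.stack([state.count[:, :, NEVER], state.count[:, :, CURRENT],
                        state.count[:, :, FORMER0:].sum(axis=2)])
        new = np.stack([nxt.count[:, :, NEVER], nxt.count[:, :, CURRENT],
                        nxt.count[:, :, FORMER0:].sum(axis=2)])
        np.testing.assert_allclose(new[:, 1:], old[:, :-1], atol=1e-12)
        np.testing.assert_allclose(
            nxt.count[0].sum(axis=-1), b.demography.newborns_in_step(1))
        assert exits.sum() == pytest.approx(state.count[-1].sum())

    def test_mass_conservation_each_step(self, fixture_bundle, dutch_bundle,
                                         max_runs):
        cases = [(run_projection(fixture_bundle, horizon=8), fixture_bundle),
                 (max_runs["table1_max_price"], dutch_bundle)]
        for res, b in cases:
            for i in range(res.horizon):
                rhs = (res.states[i].count.sum() - res.deaths[i].sum()
                       - res.exits[i].sum()
                       + b.demography.newborns_in_step(i + 1).sum())
                assert res.states[i + 1].count.sum() == pytest.approx(rhs, rel=1e-9)

    def test_class_fractions_remain_distribution(self, max_runs):
        for res in max_runs.values():
            for state in res.states[::10]:
                total = state.count.sum(axis=2)
                assert np.all(state.count >= -1e-9)
                frac_sum = np.where(total > 0, state.count.sum(axis=2) / total, 1.0)
                np.testing.assert_allclose(frac_sum, 1.0, atol=1e-9)


class TestRunProjection:
    def test_reference_run_is_deterministic(self, fixture_bundle):
        r1 = run_projection(fixture_bundle, horizon=5)
        r2 = run_projection(fixture_bundle, horizon=5)
        for s1, s2 in zip(r1.states, r2.states):
            np.testing.assert_array_equal(s1.count, s2.count)
            np.testing.assert_array_equal(s1.disease_prev, s2.disease_prev)
        np.testing.assert_array_equal(r1.deaths, r2.deaths)

    def test_cessation_lowers_current_smoking_everywhere(self, fixture_bundle):
        spec = ts.ScenarioSpec(variant="cessation", quit_or=2.0,
                               target_ages=(16, 50))
        ref = run_projection(fixture_bundle, horizon=10)
        ces = run_projection(fixture_bundle, spec, horizon=10)
        diffs = []
        for s_r, s_c in zip(ref.states[1:], ces.states[1:]):
            cur_r, cur_c = s_r.count[:, :, CURRENT], s_c.count[:, :, CURRENT]
            assert np.all(cur_c <= cur_r + 1e-9)
            diffs.append((cur_r - cur_c).max())
        assert max(diffs) > 0.0

    def test_smoking_neutral_when_all_rr_one(self, fixture_bundle):
        """With all RRs at 1 every scenario matches the reference series."""
        b = fixture_bundle.copy()
        b.mortality.rr_allcause_current[:] = 1.0
        b.mortality.rr_allcause_former[:] = 1.0
        for d in b.diseases:
            d.rr_current[:] = 1.0
            d.rr_former[:] = 1.0
        ref = run_projection(b, horizon=10)
        for spec in (ts.ScenarioSpec(variant="cessation", quit_or=3.0),
                     ts.get_preset("table1_max_price")):
            scen = run_projection(b, spec, horizon=10)
            np.testing.assert_allclose(
                scen.deaths.sum(axis=(1, 2)), ref.deaths.sum(axis=(1, 2)),
                rtol=1e-9)
            for s_r, s_c in zip(ref.states, scen.states):
                np.testing.assert_allclose(
                    (s_c.count * s_c.disease_prev).sum(axis=(1, 2, 3)),
                    (s_r.count * s_r.disease_prev).sum(axis=(1, 2, 3)),
                    rtol=1e-9)

    def test_rr_recovery_from_year_one_incidence(self, fixture_bundle):
        """Simulated current/never incidence ratio recovers the input RR."""
        b = _zeroed(fixture_bundle)
        for d, src in zip(b.diseases, fixture_bundle.diseases):
            d.incidence.values[:] = src.incidence.values
        calib = Calibration.from_bundle(b)
        state = engine.initial_state(b, b, calib)
        nxt, _, _ = step_year(state, b, calib)
        for j, d in enumerate(b.diseases):
            a = 40  # an age with nonzero incidence and both classes occupied
            p0 = state.disease_prev[j, a - 1]
            p1 = nxt.disease_prev[j, a]
            inc = (p1 - p0) / (1.0 - p0)
            ratio = inc[:, CURRENT] / inc[:, NEVER]
            np.testing.assert_allclose(ratio, d.rr_current[a - 1], rtol=1e-9)

    def test_zero_horizon_returns_baseline_only(self, fixture_bundle):
        res = run_projection(fixture_bundle, horizon=0)
        assert len(res.states) == 1 and res.deaths.shape[0] == 0

    def test_infeasible_mortality_raises(self, fixture_bundle):
        b = fixture_bundle.copy()
        b.mortality.m_total.values[:] = 1e-6   # far below disease mortality
        with pytest.raises(InfeasibleInputError):
            run_projection(b, horizon=1)
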