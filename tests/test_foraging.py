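"""Foraging: visitation rate, preference movement, compartment fluxes."""

import math

import numpy as np
import pytest

from kiwipol import (
    PollinatorParams,
    PollinatorState,
    deposit_visit_rates,
    state_derivative,
    stay_probability,
    visitation_rate,
)


class TestVisitationRate:
    def test_zero_without_flowers(self):
        assert visitation_rate(0, 0, PollinatorParams()) == 0.0

    def test_direct_evaluation(self):
        # alpha=480, beta=0.0011, 1000 open flowers -> 480000/529 per day
        got = visitation_rate(400, 600, PollinatorParams())
        assert got == pytest.approx(480_000 / 529, rel=1e-12)

    def test_saturates_at_inverse_handling_time(self):
        p = PollinatorParams()
        big = visitation_rate(5e8, 5e8, p)
        assert big == pytest.approx(1 / 0.0011, rel=1e-4)
        assert big < 1 / 0.0011

    def test_strictly_increasing_in_flowers(self):
        p = PollinatorParams()
        xs = np.linspace(1, 1e6, 200)
        vals = [visitation_rate(x / 2, x / 2, p) for x in xs]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            visitation_rate(-1, 10, PollinatorParams())


class TestStayProbability:
    def test_measured_male_stay_probability_at_even_split(self):
        # delta calibrated so a 1:1 orchard gives the observed 0.957
        assert stay_probability(1, 2, 0.0634) == pytest.approx(0.957, abs=5e-4)

    def test_no_preference_reduces_to_share(self, rng):
        for _ in range(20):
            share = rng.uniform(0.01, 0.99)
            assert stay_probability(share, 1.0, 1.0) == pytest.approx(share)

    def test_zero_exponent_always_stays(self):
        for share in (0.01, 0.5, 0.99):
            assert stay_probability(share, 1.0, 0.0) == 1.0

    def test_no_flowers_convention(self):
        assert stay_probability(0, 0, 0.5) == 1.0

    def test_switch_probability_monotone_in_share_and_preference(self):
        shares = np.linspace(0.05, 0.95, 30)
        for pref in (0.0634, 0.3, 1.0):
            switch = [1 - stay_probability(s, 1.0, pref) for s in shares]
            assert np.all(np.diff(switch) < 0)  # more own-sex, less switching
        for share in (0.2, 0.5, 0.8):
            by_pref = [1 - stay_probability(share, 1.0, p)
                       for p in (0.05, 0.3, 0.7, 1.0)]
            assert np.all(np.diff(by_pref) > 0)  # weaker preference, more switch

    def test_rejects_bad_share(self):
        with pytest.raises(ValueError):
            stay_probability(3.0, 2.0, 0.5)


def reference_derivative(state, m, f, p):
    """Independent term-by-term evaluation of the compartment system."""
    V = p.search_rate * (m + f) / (1 + p.search_rate * p.handling_time * (m + f))
    sm = (m / (m + f)) ** p.pref_male
    sf = (f / (m + f)) ** p.pref_female
    p1, p2, p3, pf = state
    return (
        V * ((1 - sf) * (p2 + p3 + pf) - (1 - sm) * p1),
        V * ((1 - sm) * p1 - (1 - sf) * p2 - sf * p2),
        V * (sf * p2 - (1 - sf) * p3 - sf * p3),
        V * (sf * p3 - (1 - sf) * pf),
    )


class TestStateDerivative:
    def test_components_conserve_total(self, rng):
        p = PollinatorParams()
        for _ in range(50):
            state = PollinatorState(*rng.uniform(0, 5000, 4))
            m, f = rng.uniform(0, 1e6, 2)
            d = state_derivative(state, m, f, p)
            scale = max(abs(x) for x in d) or 1.0
            assert sum(d) == pytest.approx(0.0, abs=1e-9 * scale)

    def test_all_flow_to_high_load_without_female_flowers(self):
        p = PollinatorParams()
        d = state_derivative(PollinatorState(100, 200, 300, 400), 1e5, 0, p)
        assert d.high_load > 0
        assert d.mid_load < 0 and d.low_load < 0 and d.no_load < 0
        # female-visit channels are silent
        assert deposit_visit_rates(
            PollinatorState(100, 200, 300, 400), 1e5, 0, p) == (0, 0, 0)

    def test_matches_independent_hand_evaluation(self):
        p = PollinatorParams()
        state = PollinatorState(0, 0, 0, 3600)
        got = state_derivative(state, 100_000, 100_000, p)
        want = reference_derivative(state, 100_000, 100_000, p)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-12)

    def test_matches_hand_evaluation_on_random_states(self, rng):
        p = PollinatorParams(search_rate=900, handling_time=0.002,
                             pref_male=0.3, pref_female=0.8)
        for _ in range(30):
            state = PollinatorState(*rng.uniform(0, 4000, 4))
            m, f = rng.uniform(10, 1e6, 2)
            got = state_derivative(state, m, f, p)
            want = reference_derivative(state, m, f, p)
            for g, w in zip(got, want):
                assert g == pytest.approx(w, rel=1e-12, abs=1e-9)

    def test_rejects_non_finite_state(self):
        with pytest.raises(ValueError):
            state_derivative(PollinatorState(math.nan, 0, 0, 0), 10, 10,
                             PollinatorParams())


class TestDepositVisitRates:
    def test_zero_without_loaded_pollinators(self):
        p = PollinatorParams()
        assert deposit_visit_rates(PollinatorState(0, 0, 0, 5000),
                                   1e5, 1e5, p) == (0.0, 0.0, 0.0)

    def test_rates_are_compartment_fluxes(self, rng):
        """The three deposit channels are exactly the downward fluxes.

        Rebuild the derivative from the reported rates plus the
        male-return fluxes and compare with state_derivative.
        """
        p = PollinatorParams()
        for _ in range(30):
            state = PollinatorState(*rng.uniform(0, 4000, 4))
            m, f = rng.uniform(10, 1e6, 2)
            r1, r2, r3 = deposit_visit_rates(state, m, f, p)
            V = visitation_rate(m, f, p)
            back = 1 - stay_probability(f, m + f, p.pref_female)
            d = state_derivative(state, m, f, p)
            assert d.mid_load == pytest.approx(
                r1 - r2 - V * back * state.mid_load, rel=1e-10, abs=1e-9)
            assert d.low_load == pytest.approx(
                r2 - r3 - V * back * state.low_load, rel=1e-10, abs=1e-9)
            assert d.no_load == pytest.approx(
                r3 - V * back * state.no_load, rel=1e-10, abs=1e-9)

    def test_no_preference_limit_splits_by_share(self):
        """With delta = epsilon = 1 movement follows flower shares exactly."""
        p = PollinatorParams(pref_male=1.0, pref_female=1.0)
        state = PollinatorState(1000, 500, 250, 100)
        m, f = 3e5, 1e5
        V = visitation_rate(m, f, p)
        r1, r2, r3 = deposit_visit_rates(state, m, f, p)
        assert r1 == pytest.approx(V * (f / (m + f)) * 1000, rel=1e-12)
        assert r2 == pytest.approx(V * (f / (m + f)) * 500, rel=1e-12)
        assert r3 == pytest.approx(V * (f / (m + f)) * 250, rel=1e-12)


class TestPollinatorParams:
    @pytest.mark.parametrize("bad", [
        dict(search_rate=0), dict(search_rate=-1), dict(handling_time=-0.1),
        dict(pref_male=1.5), dict(pref_female=-0.2), dict(density=-1),
    ])
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            PollinatorParams(**bad)
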