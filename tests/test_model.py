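"""Mechanism ODE model: rate law, integration, half-life, conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssredox.model import (
    HalfLife,
    RateConstants,
    SystemState,
    TimeCourse,
    conversion_fraction,
    half_life,
    rate_equations,
    second_order_ss,
    simulate,
)

conc = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)
rate2 = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestRateEquations:
    def test_null_mechanism_gives_zero_derivatives(self):
        state = SystemState(ss=1.3, sh=0.4, red=2.0, ox=0.1, o2=0.05, precipitated=0.2)
        dy = rate_equations(state, RateConstants(0.0, 0.0, 0.0, 0.0))
        assert all(v == 0.0 for v in dy.values())

    def test_unit_mass_action_reduction(self):
        dy = rate_equations(SystemState(ss=1.0, red=2.0), RateConstants(k1=1.0))
        assert dy["ss"] == pytest.approx(-2.0)
        assert dy["sh"] == pytest.approx(2.0)
        assert dy["red"] == pytest.approx(-2.0)
        assert dy["ox"] == pytest.approx(2.0)
        assert dy["o2"] == 0.0 and dy["precipitated"] == 0.0

    def test_reoxidation_and_oxygen_ingress(self):
        # d(ss)/dt = +k2 sh o2; d(o2)/dt = -k2 sh o2 + k4
        state = SystemState(ss=0.0, sh=2.0, o2=0.1)
        dy = rate_equations(state, RateConstants(k1=0.0, k2=0.5, k4=0.02))
        assert dy["ss"] == pytest.approx(0.1)
        assert dy["sh"] == pytest.approx(-0.1)
        assert dy["o2"] == pytest.approx(-0.08)

    @given(
        ss=conc, sh=conc, red=conc, o2=conc,
        k1=rate2, k2=rate2, k3=rate2, k4=st.floats(min_value=0.0, max_value=0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_rate_law_conserves_pools(self, ss, sh, red, o2, k1, k2, k3, k4):
        """Protein (ss+sh+precipitated) and reductant (red+ox) pool
        derivatives sum to zero under any mass-action rates."""
        dy = rate_equations(
            SystemState(ss=ss, sh=sh, red=red, o2=o2), RateConstants(k1, k2, k3, k4)
        )
        assert dy["ss"] + dy["sh"] + dy["precipitated"] == pytest.approx(0.0, abs=1e-12)
        assert dy["red"] + dy["ox"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(k1=-1.0)
        with pytest.raises(ValueError):
            SystemState(ss=-0.1)


class TestSimulate:
    def test_null_mechanism_holds_initial_state(self):
        initial = SystemState(ss=1.0, sh=0.2, red=3.0, o2=0.1)
        course = simulate(RateConstants(0.0), initial, np.linspace(0, 100, 11))
        assert np.allclose(course.states, initial.as_array(), atol=1e-12)

    def test_matches_second_order_closed_form(self):
        """Pure reduction agrees with the analytic solution to 1e-6 relative.

        Independent oracle: ss(t) = ss0 d / (red0 e^{k1 d t} - ss0), d = red0-ss0.
        """
        k1, ss0, red0 = 0.259, 1.7, 3.4
        t = np.linspace(0.0, 20.0, 100)
        course = simulate(RateConstants(k1=k1), SystemState(ss=ss0, red=red0), t)
        d = red0 - ss0
        analytic = ss0 * d / (red0 * np.exp(k1 * d * t) - ss0)
        assert np.max(np.abs(course.ss - analytic) / analytic) < 1e-6
        # spot value computed by hand from the closed form
        spot = simulate(RateConstants(k1=k1), SystemState(ss=ss0, red=red0),
                        np.array([0.0, 0.921]))
        assert spot.ss[-1] == pytest.approx(0.85, abs=5e-4)

    def test_second_order_ss_helper_agrees_with_direct_formula(self):
        t = np.linspace(0, 5, 7)
        expected = 1.7 * 1.7 / (3.4 * np.exp(0.259 * 1.7 * t) - 1.7)
        assert np.allclose(second_order_ss(t, 0.259, 1.7, 3.4), expected, rtol=1e-12)
        # equal-concentration limit: ss0/(1 + k1 ss0 t)
        assert np.allclose(second_order_ss(t, 0.5, 2.0, 2.0), 2.0 / (1 + t), rtol=1e-12)

    def test_precipitation_only_is_exact_first_order_decay(self):
        k3, sh0 = 0.05, 2.0
        t = np.linspace(0.0, 100.0, 50)
        course = simulate(RateConstants(k1=0.0, k3=k3), SystemState(ss=0.0, sh=sh0), t)
        assert np.allclose(course.sh, sh0 * np.exp(-k3 * t), rtol=1e-7, atol=1e-10)
        assert np.allclose(course.species("precipitated"), sh0 - course.sh, atol=1e-8)

    @given(
        k1=st.floats(1e-4, 1e-1), k2=st.floats(0.0, 0.5), k3=st.floats(0.0, 0.01),
        k4=st.floats(0.0, 1e-4), ss0=st.floats(0.05, 2.0), red_excess=st.floats(1.0, 20.0),
    )
    @settings(max_examples=15, deadline=None)
    def test_mass_conservation_over_long_horizon(self, k1, k2, k3, k4, ss0, red_excess):
        """Protein and reductant pools drift < 1e-6 relative over 1e4 min."""
        initial = SystemState(ss=ss0, red=red_excess * ss0, o2=0.05)
        t = np.linspace(0.0, 1e4, 200)
        course = simulate(RateConstants(k1, k2, k3, k4), initial, t)
        protein = course.ss + course.sh + course.species("precipitated")
        reductant = course.species("red") + course.species("ox")
        scale = max(initial.total_protein, initial.total_reductant)
        assert np.abs(protein - initial.total_protein).max() < 1e-6 * scale
        assert np.abs(reductant - initial.total_reductant).max() < 1e-6 * scale

    def test_ss_monotone_without_reoxidation(self):
        t = np.linspace(0.0, 500.0, 100)
        course = simulate(
            RateConstants(k1=5e-3, k3=1e-3), SystemState(ss=1.0, red=1.5), t
        )
        assert np.all(np.diff(course.ss) <= 1e-12)

    def test_oxygen_monotone_with_pure_ingress(self):
        t = np.linspace(0.0, 100.0, 20)
        course = simulate(
            RateConstants(k1=0.0, k4=1e-3), SystemState(ss=1.0, o2=0.01), t
        )
        assert np.all(np.diff(course.species("o2")) >= -1e-12)
        assert course.species("o2")[-1] == pytest.approx(0.01 + 1e-3 * 100.0, rel=1e-8)

    def test_oxygen_cap_stops_ingress(self):
        t = np.linspace(0.0, 1000.0, 50)
        course = simulate(
            RateConstants(k1=0.0, k4=1e-3), SystemState(ss=1.0, o2=0.0), t, o2_cap=0.3
        )
        assert course.species("o2")[-1] <= 0.3 + 1e-6

    def test_initial_state_returned_exactly(self):
        initial = SystemState(ss=0.113, red=2.034)
        course = simulate(RateConstants(k1=8.03e-4), initial, np.array([0.0, 10.0]))
        assert np.array_equal(course.states[0], initial.as_array())

    def test_bad_time_grids_rejected(self):
        initial = SystemState(ss=1.0, red=1.0)
        with pytest.raises(ValueError):
            simulate(RateConstants(1e-3), initial, np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            simulate(RateConstants(1e-3), initial, np.array([0.0, 2.0, 1.0]))


class TestHalfLife:
    def test_reference_excess_reductant_case(self):
        # ln(2 - 0.113/2.034)/(8.03e-4 * (2.034 - 0.113)) evaluated directly
        hl = half_life(8.03e-4, 0.113, 2.034)
        assert hl.defined
        assert hl.value == pytest.approx(431.1, rel=1e-3)

    def test_equal_concentrations_limit(self):
        assert half_life(1.0, 1.0, 1.0).value == pytest.approx(1.0)

    def test_undefined_beyond_twofold_protein_excess(self):
        hl = half_life(1.0, 3.0, 1.0)
        assert not hl.defined and hl.value is None

    def test_protein_excess_within_twofold_continues_same_formula(self):
        # c_ss0 = 1.5, c_red0 = 1: ln(2 - 1.5)/(k1 (1 - 1.5)); both the log
        # argument and the difference flip sign, so the value stays positive
        hl = half_life(0.2, 1.5, 1.0)
        assert hl.value == pytest.approx(math.log(0.5) / (0.2 * -0.5), rel=1e-12)

    @pytest.mark.parametrize("ss0,red0", [(1.7, 3.4), (0.113, 2.034), (1.5, 1.0)])
    def test_consistent_with_simulated_half_crossing(self, ss0, red0):
        """The analytic half-life matches the time at which the integrated
        SS trajectory crosses ss0/2, within 0.1%."""
        k1 = 0.02
        hl = half_life(k1, ss0, red0)
        t = np.linspace(0.0, 3.0 * hl.value, 4000)
        course = simulate(RateConstants(k1=k1), SystemState(ss=ss0, red=red0), t)
        crossing = np.interp(-ss0 / 2.0, -course.ss, t)  # ss decreasing
        assert crossing == pytest.approx(hl.value, rel=1e-3)

    def test_nonpositive_inputs_rejected(self):
        for args in [(0.0, 1.0, 1.0), (1.0, 0.0, 1.0), (1.0, 1.0, -1.0)]:
            with pytest.raises(ValueError):
                half_life(*args)


class TestConversionFraction:
    def test_starts_at_zero_for_all_oxidized(self):
        course = simulate(
            RateConstants(k1=1e-3), SystemState(ss=1.0, red=2.0), np.linspace(0, 10, 5)
        )
        assert conversion_fraction(course)[0] == 0.0

    def test_complete_reduction_limit(self):
        course = simulate(
            RateConstants(k1=1e-2), SystemState(ss=0.1, red=2.0),
            np.linspace(0.0, 5e3, 100),
        )
        assert conversion_fraction(course)[-1] == pytest.approx(1.0, abs=1e-6)

    def test_reoxidation_keeps_conversion_below_one(self):
        """Sustained O2 ingress with active reoxidation leaves part of the
        protein oxidized at steady state."""
        course = simulate(
            RateConstants(k1=8.03e-4, k2=0.1, k4=1.5e-5),
            SystemState(ss=0.113, red=2.034, o2=0.05),
            np.linspace(0.0, 8000.0, 200),
        )
        terminal = conversion_fraction(course)[-1]
        assert 0.5 < terminal < 0.999

    def test_flags_undefined_points(self):
        times = np.array([0.0, 1.0])
        states = np.zeros((2, 6))
        states[:, 5] = 1.0  # everything precipitated
        with pytest.warns(RuntimeWarning, match="no soluble protein"):
            out = conversion_fraction(TimeCourse(times=times, states=states))
        assert np.isnan(out).all()


def test_halflife_marker_truthiness():
    assert HalfLife(5.0).defined and not HalfLife(None).defined
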