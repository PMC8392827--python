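"""Simulator tests: profiles, integration fidelity, qualitative physics."""

import numpy as np
import pytest

from fermkin import (
    FermentationState,
    InvalidInputError,
    RangeError,
    TemperatureCoupling,
    constant_profile,
    evaluate_profile,
    iae,
    make_step_profile,
    simulate,
)
from fermkin.datasets import REFERENCE_COUPLING, REFERENCE_INIT, REFERENCE_KINETICS

P, C = REFERENCE_KINETICS, REFERENCE_COUPLING
INIT3 = FermentationState(0.0026, 0.009, 0.0001)


class TestTemperatureProfile:
    def test_step_is_right_continuous(self):
        prof = make_step_profile(22.0, 27.0, 3.0)
        assert prof.value(2.99) == 22.0
        assert prof.value(3.0) == 27.0
        assert prof.value(24.0) == 27.0

    @pytest.mark.parametrize("args, expected", [
        ((22.0, 22.0, 5.0), 22.0),   # equal temps degenerate to constant
        ((22.0, 27.0, 0.0), 27.0),   # step at t=0 is constant at the target
    ])
    def test_degenerate_steps(self, args, expected):
        prof = make_step_profile(*args)
        assert prof.is_constant
        assert prof.value(0.0) == expected == prof.value(12.0)

    def test_single_breakpoint_holds_forever(self):
        assert evaluate_profile(constant_profile(22.0), 100.0) == 22.0

    def test_negative_time_rejected(self):
        with pytest.raises(RangeError):
            constant_profile(22.0).value(-0.1)

    def test_temperature_outside_validity_window(self):
        with pytest.raises(RangeError):
            constant_profile(60.0)

    def test_breakpoints_must_increase_from_zero(self):
        from fermkin import TemperatureProfile

        with pytest.raises(InvalidInputError):
            TemperatureProfile(((1.0, 22.0),))
        with pytest.raises(InvalidInputError):
            TemperatureProfile(((0.0, 22.0), (0.0, 25.0)))


class TestSimulate:
    def test_initial_state_returned_exactly(self):
        traj = simulate(P, INIT3, t_end=24.0, output_times=[0.0])
        assert traj.x1[0] == INIT3.x1
        assert traj.x2[0] == INIT3.x2
        assert traj.x3[0] == INIT3.x3

    def test_total_biomass_substrate_conserved(self):
        traj = simulate(P, INIT3)
        assert np.max(np.abs(traj.x1 + traj.x2 - 0.0116)) < 1e-7

    def test_conservation_under_step_protocol(self):
        traj = simulate(P, REFERENCE_INIT, coupling=C,
                        profile=make_step_profile(22.0, 27.0, 3.0))
        total0 = REFERENCE_INIT.x1 + REFERENCE_INIT.x2
        assert np.max(np.abs(traj.x1 + traj.x2 - total0)) < 1e-9

    def test_four_state_reduces_to_fundamental_at_constant_reference(self):
        t3 = simulate(P, INIT3)
        t4 = simulate(P, REFERENCE_INIT, coupling=C, profile=constant_profile(22.0))
        assert np.max(np.abs(t4.x3 - t3.x3)) < 1e-8

    def test_zero_coupling_matches_fundamental_even_off_reference(self):
        c0 = TemperatureCoupling(0.0, 0.0, 0.1, 22.0)
        t3 = simulate(P, INIT3)
        t4 = simulate(P, REFERENCE_INIT, coupling=c0, profile=constant_profile(27.0))
        assert np.max(np.abs(t4.x3 - t3.x3)) < 1e-8

    def test_solver_tolerance_convergence(self):
        a = simulate(P, INIT3).x3[-1]
        b = simulate(P, INIT3, rtol=5e-9, atol=5e-11).x3[-1]
        assert abs(a - b) < 1e-9

    def test_heating_follows_first_order_lag(self):
        """The simulated temperature completes 63.2% of a reference step in
        one time constant (6 min)."""
        grid = np.linspace(0.0, 1.0, 601)
        traj = simulate(P, REFERENCE_INIT, coupling=C,
                        profile=constant_profile(27.0), t_end=1.0, output_times=grid)
        frac = (np.interp(C.t_theta_cs, grid, traj.temp) - 22.0) / 5.0
        assert frac == pytest.approx(1.0 - np.exp(-1.0), abs=1e-3)

    def test_range_error_reports_time(self):
        hot = TemperatureCoupling(2.0, 0.0, 0.1, 22.0)
        with pytest.raises(RangeError, match="t="):
            simulate(P, REFERENCE_INIT, coupling=hot, profile=constant_profile(10.0))

    def test_invalid_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate(P, INIT3, t_end=0.0)
        with pytest.raises(InvalidInputError):
            simulate(P, INIT3, t_end=1.0, output_times=[0.0, 2.0])


@pytest.fixture(scope="module")
def constant_runs():
    return {
        T: simulate(P, REFERENCE_INIT, coupling=C, profile=constant_profile(T))
        for T in (20.0, 22.0, 24.0, 26.0)
    }


class TestQualitativePhysics:
    """The experimental findings the model must reproduce."""

    def test_warmer_fermentations_produce_more_co2(self, constant_runs):
        finals = [constant_runs[T].x3[-1] for T in (20.0, 22.0, 24.0, 26.0)]
        assert np.all(np.diff(finals) > 0)

    def test_co2_curves_ordered_pointwise_in_temperature(self, constant_runs):
        for lo, hi in [(20.0, 22.0), (22.0, 24.0), (24.0, 26.0)]:
            a, b = constant_runs[lo].x3, constant_runs[hi].x3
            assert np.all(b[1:] > a[1:])

    def test_temperature_step_accelerates_fermentation(self, constant_runs):
        base = constant_runs[22.0]
        stepped = simulate(P, REFERENCE_INIT, coupling=C,
                           profile=make_step_profile(22.0, 27.0, 3.0))
        after = stepped.times >= 3.0
        assert np.all(stepped.x3[after] >= base.x3[after])
        assert stepped.x3[-1] > base.x3[-1] + 10 * 1e-10

    def test_earlier_step_deviates_more(self, constant_runs):
        """A step during the fast-growth phase perturbs the CO2 course more
        than the same step applied later."""
        base = constant_runs[22.0]
        s3 = simulate(P, REFERENCE_INIT, coupling=C,
                      profile=make_step_profile(22.0, 27.0, 3.0))
        s6 = simulate(P, REFERENCE_INIT, coupling=C,
                      profile=make_step_profile(22.0, 27.0, 6.0))
        d3 = iae(s3.x3, base.x3, base.times)
        d6 = iae(s6.x3, base.x3, base.times)
        assert d3 > d6
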