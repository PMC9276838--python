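"""Electrical model: potential, power density, power matching, logs."""

import io

import numpy as np
import pytest

from rfasim.electrical import (ElectricalSolveError, PowerLogError,
                               PowerTrace, default_conductivity,
                               read_power_log, scale_to_recorded_power,
                               solve_drive, solve_potential)
from rfasim.fixtures import make_analytic_scene, make_power_trace
from rfasim.grid import discretize_scene


@pytest.fixture(scope="module")
def sphere_setup():
    """Concentric spheres a=2, b=20 at 1 mm: small enough for unit tests."""
    fx = make_analytic_scene("concentric_spheres", a=2.0, b=20.0,
                             sigma=0.333)
    dom = discretize_scene(fx.scene, 1.0)
    cond = default_conductivity(dom, 0.333)
    state = solve_drive(dom, cond)
    return fx, dom, cond, state


class TestSolvePotential:
    def test_matches_concentric_sphere_closed_form(self, sphere_setup):
        fx, dom, cond, state = sphere_setup
        r = np.linalg.norm(dom.free_centers(), axis=1)
        interior = (r > 3.0) & (r < 18.0)
        exact = fx.truth(r[interior])
        err = np.abs(state.potential[interior] - exact)
        assert err.max() <= 0.02  # within 2% of V0 = 1 V

    def test_zero_drive_gives_zero_field(self, sphere_setup):
        _, dom, cond, _ = sphere_setup
        phi = solve_potential(dom, cond, 0.0)
        assert not phi.any()

    def test_potential_invariant_to_uniform_conductivity_scaling(
            self, sphere_setup):
        _, dom, cond, state = sphere_setup
        state2 = solve_drive(dom, 2.0 * cond)
        np.testing.assert_allclose(state2.potential, state.potential,
                                   atol=1e-6)

    def test_potential_within_drive_bounds(self, sphere_setup):
        _, _, _, state = sphere_setup
        assert state.potential.min() >= -1e-10
        assert state.potential.max() <= 1.0 + 1e-10

    def test_missing_ground_raises(self):
        from rfasim.geometry import build_box_scene
        dom = discretize_scene(build_box_scene((10., 10., 10.)), 1.0)
        with pytest.raises(ElectricalSolveError):
            solve_potential(dom, np.ones(dom.n_free), 1.0)


class TestPowerDensity:
    def test_density_nonnegative_and_integrates_to_total(self, sphere_setup):
        _, dom, _, state = sphere_setup
        assert state.power_density.min() >= 0.0
        integral = state.power_density.sum() * dom.cell_volume_m3
        assert integral == pytest.approx(state.total_power, rel=1e-12)

    def test_spreading_resistance_close_to_closed_form(self, sphere_setup):
        fx, _, _, state = sphere_setup
        exact = fx.meta["resistance_ohm"]
        assert state.effective_impedance == pytest.approx(exact, rel=0.05)

    def test_impedance_inverse_in_conductivity(self, sphere_setup):
        _, dom, cond, state = sphere_setup
        state2 = solve_drive(dom, 2.0 * cond)
        assert state2.effective_impedance == pytest.approx(
            state.effective_impedance / 2.0, rel=1e-6)


class TestScaleToRecordedPower:
    def test_densities_scale_linearly(self, sphere_setup):
        _, _, _, state = sphere_setup
        scaled = scale_to_recorded_power(state, 50.0)
        np.testing.assert_allclose(
            scaled.power_density,
            state.power_density * (50.0 / state.total_power), rtol=1e-12)

    def test_total_power_matches_target_exactly(self, sphere_setup):
        _, dom, _, state = sphere_setup
        scaled = scale_to_recorded_power(state, 30.0)
        assert scaled.total_power == pytest.approx(30.0, rel=1e-12)
        integral = scaled.power_density.sum() * dom.cell_volume_m3
        assert integral == pytest.approx(30.0, rel=1e-9)

    def test_potential_scales_with_sqrt(self, sphere_setup):
        _, _, _, state = sphere_setup
        scaled = scale_to_recorded_power(state, 4.0 * state.total_power)
        np.testing.assert_allclose(scaled.potential, 2.0 * state.potential,
                                   rtol=1e-12)

    def test_zero_target_zeroes_fields(self, sphere_setup):
        _, _, _, state = sphere_setup
        z = scale_to_recorded_power(state, 0.0)
        assert z.total_power == 0.0
        assert not z.power_density.any()

    def test_power_matched_at_every_step_of_a_trace(self, sphere_setup):
        """Energy bookkeeping: the rescaled drive reproduces each recorded
        sample to 1e-6 relative over a full 300-sample trace."""
        _, dom, _, state = sphere_setup
        trace = make_power_trace(duration_s=299.0, plateau_W=90.0,
                                 noise_sd=3.0, seed=11)
        worst = 0.0
        for t in trace.timestamps:
            target = float(trace.power_at(t))
            scaled = scale_to_recorded_power(state, target)
            integral = scaled.power_density.sum() * dom.cell_volume_m3
            if target > 0:
                worst = max(worst, abs(integral - target) / target)
        assert worst <= 1e-6


class TestPowerTrace:
    def test_round_trip_bit_identical(self, tmp_path):
        trace = make_power_trace(duration_s=120.0, plateau_W=90.0,
                                 noise_sd=2.0, seed=5)
        path = tmp_path / "log.csv"
        trace.to_csv(path)
        back = read_power_log(path)
        np.testing.assert_array_equal(back.timestamps, trace.timestamps)
        np.testing.assert_array_equal(back.applied_power, trace.applied_power)

    def test_duration_and_count(self):
        trace = make_power_trace(duration_s=299.0)
        assert len(trace.timestamps) == 300
        assert trace.duration == pytest.approx(299.0)

    def test_repeated_timestamp_rejected_with_row(self):
        csv = "time_s,power_W\n0,10\n1,20\n1,30\n"
        with pytest.raises(PowerLogError, match="row 3"):
            read_power_log(io.StringIO(csv))

    def test_negative_power_rejected(self):
        csv = "time_s,power_W\n0,10\n1,-5\n"
        with pytest.raises(PowerLogError, match="negative"):
            read_power_log(io.StringIO(csv))

    def test_empty_file_rejected(self):
        with pytest.raises(PowerLogError):
            read_power_log(io.StringIO(""))

    def test_zero_order_hold(self):
        trace = PowerTrace(np.array([0.0, 1.0, 2.0]),
                           np.array([10.0, 20.0, 30.0]))
        assert trace.power_at(0.5) == 10.0
        assert trace.power_at(1.0) == 20.0
        assert trace.power_at(5.0) == 30.0
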