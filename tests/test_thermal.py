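"""Bioheat marching: closed-form checks, vessel sink, evaporation, energy."""

import numpy as np
import pytest

from rfasim import geometry as geo
from rfasim.benchmarks import (perfused_relaxation_benchmark,
                               slab_conduction_benchmark)
from rfasim.fixtures import make_analytic_scene
from rfasim.geometry import VesselSpec, build_box_scene
from rfasim.grid import discretize_scene
from rfasim.thermal import (AGAR_PROPERTIES, ThermalProperties, ThermalSolver,
                            vessel_heat_transfer_coefficient)


@pytest.fixture(scope="module")
def insulated_box():
    return discretize_scene(build_box_scene((16.0, 16.0, 16.0)), 2.0)


class TestStepTemperature:
    def test_uniform_no_source_is_steady(self, insulated_box):
        solver = ThermalSolver(insulated_box,
                               {geo.TISSUE: AGAR_PROPERTIES})
        state = solver.initial_state(37.0)
        state = solver.step(state, np.zeros(insulated_box.n_free), 1.0)
        np.testing.assert_allclose(state.temperature, 37.0, atol=1e-10)

    def test_perfused_relaxation_matches_scalar_ode(self):
        """Uniform heating of an insulated perfused block relaxes to
        T_a + q/(w rho_b c_b) with time constant rho c/(w rho_b c_b)."""
        res = perfused_relaxation_benchmark(resolution=8.0, n_tau=5.0,
                                            steps_per_tau=200)
        assert res.max_relative_error <= 0.01

    def test_series_slab_steady_state(self):
        """Fixed end temperatures, two conductivities in series: flux and
        profile match the harmonic-mean closed form."""
        res = slab_conduction_benchmark(resolution=1.0)
        assert res.interface_flux_W_m2 == pytest.approx(
            res.exact_flux_W_m2, rel=0.01)
        assert res.max_profile_error <= 1e-5

    def test_first_order_in_dt(self, insulated_box):
        """Backward Euler: halving dt roughly halves the temporal error;
        no oscillation at dt = 1 s."""
        props = ThermalProperties()
        fx = make_analytic_scene("perfused_box", q=5e4, props=props)
        dom = discretize_scene(fx.scene, 8.0)
        errs = {}
        for dt in (4.0, 2.0, 1.0):
            solver = ThermalSolver(dom, {geo.TISSUE: props},
                                   enable_evaporation=False)
            state = solver.initial_state(fx.scene.initial_temperature)
            t_end = 40.0
            qd = np.full(dom.n_free, 5e4)
            for _ in range(int(t_end / dt)):
                state = solver.step(state, qd, dt)
            errs[dt] = abs(float(state.temperature.mean())
                           - float(fx.truth(t_end)))
        assert errs[2.0] < errs[4.0]
        assert errs[1.0] < errs[2.0]
        # first order: error ratio ~ 2 between successive halvings
        assert errs[4.0] / errs[1.0] > 2.5

    def test_invalid_dt_rejected(self, insulated_box):
        solver = ThermalSolver(insulated_box)
        state = solver.initial_state(20.0)
        with pytest.raises(ValueError):
            solver.step(state, np.zeros(insulated_box.n_free), 0.0)


class TestVesselHeatSink:
    def test_bench_channel_coefficient(self):
        """5 mm lumen at 10.5 cm/s water: laminar (Re ~ 525), so
        h = Nu k_f / d with Nu = 3.66."""
        v = VesselSpec(centerline=np.zeros((2, 3)), diameter=5.0,
                       flow_speed=105.0)
        re = (v.flow_speed * 1e-3) * (v.diameter * 1e-3) / 1e-6
        assert re == pytest.approx(525.0)
        h = vessel_heat_transfer_coefficient(v)
        assert h == pytest.approx(3.66 * 0.60 / 0.005, rel=1e-12)

    def test_zero_flow_gives_zero_coefficient(self):
        v = VesselSpec(centerline=np.zeros((2, 3)), flow_speed=0.0)
        assert vessel_heat_transfer_coefficient(v) == 0.0

    def test_vessel_cools_everywhere_vs_no_vessel(self):
        """Heating next to a flowing channel: every shared cell is at or
        below its no-vessel counterpart at all times (monotone sink)."""
        from rfasim.fixtures import make_phantom_fixture
        scene_v, _ = make_phantom_fixture(25.0, duration_s=60.0)
        scene_0, _ = make_phantom_fixture(None, duration_s=60.0)
        dom_v = discretize_scene(scene_v, 4.0)
        dom_0 = discretize_scene(scene_0, 4.0)
        assert dom_v.shape == dom_0.shape
        props = {geo.TISSUE: AGAR_PROPERTIES}
        sol_v = ThermalSolver(dom_v, props)
        sol_0 = ThermalSolver(dom_0, props)
        st_v = sol_v.initial_state(20.0)
        st_0 = sol_0.initial_state(20.0)
        # uniform moderate heating of the whole bath
        q_v = np.full(dom_v.n_free, 2.0e5)
        q_0 = np.full(dom_0.n_free, 2.0e5)
        shared = (dom_v.free_mask & dom_0.free_mask
                  & (dom_v.material == dom_0.material))
        for _ in range(30):
            st_v = sol_v.step(st_v, q_v, 2.0)
            st_0 = sol_0.step(st_0, q_0, 2.0)
            T_v = dom_v.full_field(st_v.temperature).ravel()
            T_0 = dom_0.full_field(st_0.temperature).ravel()
            diff = T_v[shared] - T_0[shared]
            # at/below the no-vessel twin everywhere (up to solver noise)
            assert np.all(diff <= 1e-5)
        # and the cooling next to the wall is physically significant
        assert diff.min() < -0.5


class TestEvaporation:
    def _heat_block(self, enable, q=1.0e7, t_end=300.0, dt=2.0):
        dom = discretize_scene(build_box_scene((10.0, 10.0, 10.0)), 2.0)
        props = ThermalProperties(perfusion_rate=0.0, density=1000.0,
                                  specific_heat=4000.0, conductivity=0.6,
                                  water_fraction=0.8)
        solver = ThermalSolver(dom, {geo.TISSUE: props},
                               enable_perfusion=False,
                               enable_evaporation=enable)
        state = solver.initial_state(20.0)
        qd = np.full(dom.n_free, q)
        traj = []
        for _ in range(int(t_end / dt)):
            state = solver.step(state, qd, dt)
            traj.append(float(state.temperature.mean()))
        return np.asarray(traj), state, props, dt

    def test_plateau_duration_matches_latent_budget(self):
        """Sustained heating pauses in the band for ~latent energy / power
        before climbing past it."""
        traj, state, props, dt = self._heat_block(True)
        lo, hi = props.evaporation_band
        in_band = (traj >= lo) & (traj < hi)
        plateau_s = in_band.sum() * dt
        latent_per_m3 = props.latent_heat * props.water_fraction * props.density
        expected_s = latent_per_m3 / 1.0e7
        # sensible heating across the 2-degree band adds a small extra time
        extra_s = props.density * props.specific_heat * (hi - lo) / 1.0e7
        assert plateau_s == pytest.approx(expected_s + extra_s, rel=0.05)

    def test_sub_band_heating_identical_with_and_without(self):
        t_on, *_ = self._heat_block(True, q=2.0e5, t_end=100.0)
        t_off, *_ = self._heat_block(False, q=2.0e5, t_end=100.0)
        assert t_on.max() < 99.0
        np.testing.assert_allclose(t_on, t_off, atol=1e-9)

    def test_energy_conserved_through_plateau(self):
        """Input energy = stored (sensible + latent) during the plateau;
        ledger closes within 1% with no clamping engaged."""
        traj, state, props, dt = self._heat_block(True, t_end=150.0)
        lo, hi = props.evaporation_band
        assert lo <= traj[-1] < hi          # still mid-plateau
        assert state.ledger.clamp_discard == 0.0
        assert state.ledger.closure_error <= 0.01

    def test_ceiling_clamp_bounds_temperature(self):
        traj, state, props, _ = self._heat_block(True, q=5.0e6, t_end=600.0)
        assert state.temperature.max() <= props.evaporation_band[1] \
            + props.ceiling_margin + 1e-9
        assert state.ledger.clamp_discard > 0.0
        assert state.ledger.closure_error <= 0.01
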