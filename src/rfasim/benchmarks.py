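"""Closed-form solver benchmarks used by the test suite and the
reproduction script.

Each benchmark runs the actual production solvers on an analytic scene and
returns both the computed and the exact quantity, so accuracy claims are
always recomputed, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import geometry as geo
from .electrical import default_conductivity, solve_drive
from .fixtures import make_analytic_scene
from .grid import discretize_scene
from .thermal import ThermalProperties, ThermalSolver


@dataclass
class SpreadingResistanceResult:
    resolutions: tuple
    resistances_ohm: tuple
    exact_ohm: float                 # 1/(4 pi sigma a), the spreading term
    exact_finite_ohm: float          # with the outer-sphere correction
    relative_errors: tuple           # vs the spreading-resistance form
    n_free_cells: tuple


def spreading_resistance_benchmark(
        resolutions: Sequence[float] = (1.0, 0.5), *,
        a: float = 1.0, b: float = 60.0, sigma: float = 0.333,
        rtol_coarse: float = 1e-8,
        rtol_fine: float = 1e-3) -> SpreadingResistanceResult:
    """Concentric-sphere spreading resistance at a sequence of resolutions.

    Solves coarse-to-fine, warm-starting each level from the previous one
    (multiresolution continuation); the resistance is the Dirichlet-energy
    functional of the solve, so it is insensitive to the residual at the
    warm-started fine levels and a loose fine-level tolerance suffices.
    """
    fx = make_analytic_scene("concentric_spheres", a=a, b=b, sigma=sigma)
    rs, errs, sizes = [], [], []
    prev = None    # (domain, potential)
    exact_inf = fx.meta["resistance_infinite_ohm"]
    for i, h in enumerate(resolutions):
        dom = discretize_scene(fx.scene, h)
        cond = default_conductivity(dom, sigma)
        x0 = None
        if prev is not None:
            x0 = _resample_potential(prev[0], prev[1], dom)
        rtol = rtol_coarse if i == 0 else rtol_fine
        state = solve_drive(dom, cond, rtol=rtol, x0=x0)
        rs.append(state.effective_impedance)
        errs.append((state.effective_impedance - exact_inf) / exact_inf)
        sizes.append(dom.n_free)
        prev = (dom, state.potential)
    return SpreadingResistanceResult(
        resolutions=tuple(resolutions), resistances_ohm=tuple(rs),
        exact_ohm=exact_inf, exact_finite_ohm=fx.meta["resistance_ohm"],
        relative_errors=tuple(errs), n_free_cells=tuple(sizes))


def _resample_potential(dom_coarse, phi_coarse, dom_fine):
    """Nearest-cell upsampling of a free-cell potential (warm start)."""
    full = np.zeros(dom_coarse.n_cells)
    full[dom_coarse.free_mask] = phi_coarse
    full[dom_coarse.material == geo.ELECTRODE] = 1.0
    centers = dom_fine.free_centers()
    idx = np.round((centers - dom_coarse.origin) / dom_coarse.spacing).astype(int)
    idx = np.clip(idx, 0, np.asarray(dom_coarse.shape) - 1)
    flat = np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]),
                                dom_coarse.shape)
    return full[flat]


@dataclass
class PerfusedRelaxationResult:
    times: np.ndarray
    simulated: np.ndarray
    exact: np.ndarray
    max_relative_error: float
    tau_s: float


def perfused_relaxation_benchmark(*, q: float = 5.0e4,
                                  props: ThermalProperties | None = None,
                                  resolution: float = 4.0,
                                  n_tau: float = 5.0,
                                  steps_per_tau: int = 200) -> PerfusedRelaxationResult:
    """Uniformly heated, insulated, perfused block vs the scalar ODE.

    With no thermal gradients the bioheat balance reduces to
    ``rho c dT/dt = q - w rho_b c_b (T - T_a)``; the simulated uniform field
    must follow the closed-form exponential relaxation.
    """
    props = props or ThermalProperties()
    fx = make_analytic_scene("perfused_box", q=q, props=props)
    dom = discretize_scene(fx.scene, resolution)
    solver = ThermalSolver(dom, {geo.TISSUE: props},
                           enable_evaporation=False)
    state = solver.initial_state(fx.scene.initial_temperature)
    tau = fx.meta["tau_s"]
    dt = tau / steps_per_tau
    qd = np.full(dom.n_free, q)
    times, sim = [], []
    n_steps = int(np.ceil(n_tau * tau / dt))
    for _ in range(n_steps):
        state = solver.step(state, qd, dt)
        times.append(state.time)
        sim.append(float(state.temperature.mean()))
    times = np.asarray(times)
    sim = np.asarray(sim)
    exact = fx.truth(times)
    scale = max(abs(fx.meta["t_inf"] - fx.scene.initial_temperature), 1e-12)
    err = float(np.max(np.abs(sim - exact)) / scale)
    return PerfusedRelaxationResult(times=times, simulated=sim, exact=exact,
                                    max_relative_error=err, tau_s=tau)


@dataclass
class HeatSinkStudyResult:
    volumes_mm3: dict                # offset (None or mm) -> ablation volume
    deficits_mm3: dict               # offset mm -> no-vessel volume - volume
    wall_time_s: float
    ledger_closures: dict

    @property
    def monotone(self) -> bool:
        """Deficit strictly positive and strictly decreasing with offset."""
        offsets = sorted(self.deficits_mm3)
        d = [self.deficits_mm3[o] for o in offsets]
        return all(x > 0 for x in d) and all(
            d[i] > d[i + 1] for i in range(len(d) - 1))


def heat_sink_study(offsets=(25.0, 30.0, 35.0), *, resolution: float = 1.5,
                    duration_s: float = 300.0, dt: float = 1.0,
                    plateau_W: float = 90.0) -> HeatSinkStudyResult:
    """Paired phantom runs: no vessel vs flow channels at several offsets.

    The indentation the flowing channel carves out of the ablation volume
    (its deficit vs the no-vessel twin) should shrink monotonically as the
    channel moves away from the electrode.
    """
    import time as _time

    from .fixtures import make_phantom_fixture
    from .pipeline import RunConfig, simulate_ablation

    t0 = _time.perf_counter()
    cfg = RunConfig(resolution=resolution, dt=dt, tissue="agar")
    volumes, closures = {}, {}
    for off in (None, *offsets):
        scene, trace = make_phantom_fixture(off, duration_s=duration_s,
                                            plateau_W=plateau_W)
        res = simulate_ablation(scene, trace, cfg)
        volumes[off] = res.ablation.volume_mm3
        closures[off] = res.ledger_closure
    deficits = {off: volumes[None] - volumes[off] for off in offsets}
    return HeatSinkStudyResult(volumes_mm3=volumes, deficits_mm3=deficits,
                               wall_time_s=_time.perf_counter() - t0,
                               ledger_closures=closures)


@dataclass
class SlabConductionResult:
    interface_flux_W_m2: float
    exact_flux_W_m2: float
    max_profile_error: float         # deg C, vs the piecewise-linear profile


def slab_conduction_benchmark(*, k1: float = 0.5, k2: float = 2.0,
                              t_hot: float = 80.0, t_cold: float = 20.0,
                              resolution: float = 1.0,
                              length: float = 20.0) -> SlabConductionResult:
    """Two-material series slab steady state vs the harmonic-mean flux.

    Integrates the transient solver to steady state with fixed face
    temperatures and compares the through-flux and the temperature profile
    with the 1D closed form.
    """
    fx = make_analytic_scene("slab", k1=k1, k2=k2, t_hot=t_hot,
                             t_cold=t_cold, length=length)
    dom = discretize_scene(fx.scene, resolution)
    centers = dom.free_centers()
    k_field = np.where(centers[:, 0] <= length, k1, k2)
    props = ThermalProperties(perfusion_rate=0.0, density=1000.0,
                              specific_heat=1000.0, conductivity=k1)
    solver = ThermalSolver(dom, {geo.TISSUE: props},
                           enable_perfusion=False, enable_evaporation=False,
                           conductivity_field=k_field,
                           fixed_boundary_temps={geo.ELECTRODE: t_hot,
                                                 geo.GROUND: t_cold})
    state = solver.initial_state(t_cold)
    # march with a large dt to steady state (backward Euler is stable)
    L = length * 1e-3
    alpha = min(k1, k2) / (props.density * props.specific_heat)
    t_char = (2 * L) ** 2 / alpha
    dt = t_char / 20
    for _ in range(400):
        prev = state.temperature
        state = solver.step(state, np.zeros(dom.n_free), dt)
        if np.max(np.abs(state.temperature - prev)) < 1e-10 * (t_hot - t_cold):
            break
    bvals = solver.boundary_values
    fluxes = solver.conduction.boundary_fluxes(state.temperature, bvals)
    # flux through the hot face (electrode-labelled boundary edges)
    hot_edges = dom.material[dom.edges.fd_dir] == geo.ELECTRODE
    h_m = dom.spacing * 1e-3
    area = h_m ** 2 * hot_edges.sum()
    flux_sim = float(-fluxes[hot_edges].sum() / area)
    exact_profile = fx.truth(centers[:, 0])
    return SlabConductionResult(
        interface_flux_W_m2=flux_sim,
        exact_flux_W_m2=fx.meta["flux_W_m2"],
        max_profile_error=float(np.max(np.abs(state.temperature - exact_profile))))
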