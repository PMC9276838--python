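"""Quasi-static RF conduction: potential, dissipated power density, and
power-matching against a recorded generator trace.

At 460-500 kHz the tissue behaves resistively, so the potential solves
``div(sigma grad V) = 0`` with the energised electrode at V0, the return
pad at 0 V, and zero normal current elsewhere.  The generator's control
loop is not simulated: a unit-potential solve is rescaled every control
interval so the domain-integrated Joule power equals the recorded power
(the drive is linear in V0, so power scales with V0^2).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import scipy.sparse.linalg as spla

from . import geometry as geo
from .grid import DiscreteDomain, DiffusionOperator


class PowerLogError(ValueError):
    """Malformed generator power log."""


class ElectricalSolveError(RuntimeError):
    pass


@dataclass
class PowerTrace:
    """Generator output sampled at (nominally) 1 s cadence.

    ``timestamps`` in seconds, strictly increasing; ``applied_power`` in
    watts, non-negative; optional measured ``impedance`` in ohms.
    """

    timestamps: np.ndarray
    applied_power: np.ndarray
    impedance: Optional[np.ndarray] = None

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, float)
        self.applied_power = np.asarray(self.applied_power, float)
        if self.timestamps.size == 0:
            raise PowerLogError("empty power trace")
        if self.timestamps.size != self.applied_power.size:
            raise PowerLogError("timestamps and power lengths differ")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise PowerLogError(
                f"timestamps not strictly increasing at row {row + 1} "
                f"(t={self.timestamps[row]})")
        if np.any(self.applied_power < 0):
            row = int(np.argmax(self.applied_power < 0))
            raise PowerLogError(
                f"negative power at row {row + 1} "
                f"({self.applied_power[row]} W)")
        if self.impedance is not None:
            self.impedance = np.asarray(self.impedance, float)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def power_at(self, t: Union[float, np.ndarray]) -> np.ndarray:
        """Zero-order-hold lookup: the last sample at or before t."""
        idx = np.searchsorted(self.timestamps, np.asarray(t, float),
                              side="right") - 1
        idx = np.clip(idx, 0, len(self.timestamps) - 1)
        return self.applied_power[idx]

    def to_csv(self, path):
        cols = {"time_s": self.timestamps, "power_W": self.applied_power}
        if self.impedance is not None:
            cols["impedance_ohm"] = self.impedance
        # %.17g guarantees a bit-identical float round trip
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_power_log(file) -> PowerTrace:
    """Read a generator log CSV (``time_s,power_W[,impedance_ohm]``)."""
    try:
        df = pd.read_csv(file, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise PowerLogError("empty power log file") from None
    for col in ("time_s", "power_W"):
        if col not in df.columns:
            raise PowerLogError(f"power log missing required column {col!r}")
    if len(df) == 0:
        raise PowerLogError("power log has a header but no rows")
    imp = df["impedance_ohm"].to_numpy() if "impedance_ohm" in df.columns else None
    return PowerTrace(df["time_s"].to_numpy(), df["power_W"].to_numpy(), imp)


@dataclass
class ElectricalState:
    """Solved RF drive at one control interval.

    ``power_density`` is W/m^3 per free cell, derived from the per-edge
    Joule dissipation (half of each edge's ``g (dV)^2`` is deposited in
    each endpoint cell), so its volume integral equals ``total_power``
    identically.
    """

    potential: np.ndarray          # V per free cell
    power_density: np.ndarray      # W/m^3 per free cell
    total_power: float             # W
    electrode_potential: float     # V
    effective_impedance: float     # ohm
    conductivity: np.ndarray = field(repr=False, default=None)

    def scaled(self, factor: float) -> "ElectricalState":
        s = float(factor)
        return ElectricalState(
            potential=self.potential * np.sqrt(s),
            power_density=self.power_density * s,
            total_power=self.total_power * s,
            electrode_potential=self.electrode_potential * np.sqrt(s),
            effective_impedance=self.effective_impedance,
            conductivity=self.conductivity,
        )


def default_conductivity(domain: DiscreteDomain,
                         sigma_tissue: float = 0.333,
                         sigma_lumen: Optional[float] = None) -> np.ndarray:
    """Per-free-cell conductivity field (S/m) from material classes.

    The lumen (water or blood) defaults to the tissue value; the insulated
    shaft is treated as non-conducting and handled by exclusion upstream.
    """
    sig = np.full(domain.n_free, sigma_tissue)
    mat = domain.material[domain.free_mask]
    if sigma_lumen is not None:
        sig[mat == geo.VESSEL_LUMEN] = sigma_lumen
    # shaft cells are free (thermally active) but electrically insulated:
    # give them a tiny conductivity so essentially no current enters them.
    sig[mat == geo.SHAFT] = 1e-6 * sigma_tissue
    return sig


def solve_potential(domain: DiscreteDomain, conductivity: np.ndarray,
                    electrode_potential: float = 1.0, *,
                    rtol: float = 1e-8, x0: Optional[np.ndarray] = None,
                    maxiter: int = 20000) -> np.ndarray:
    """Potential (V, per free cell) for the given electrode drive.

    Dirichlet ``electrode_potential`` on the electrode cells, 0 on ground,
    natural (insulated) conditions elsewhere.  Jacobi-preconditioned CG on
    the SPD conduction operator.
    """
    if len(domain.boundary_labels.get("ground", ())) == 0:
        raise ElectricalSolveError("scene has no ground boundary; system singular")
    if len(domain.boundary_labels.get("electrode_surface", ())) == 0:
        raise ElectricalSolveError("scene has no energised electrode cells")
    op = DiffusionOperator(domain, conductivity)
    bvals = _boundary_values(domain, electrode_potential)
    rhs = op.dirichlet_rhs(bvals)
    if electrode_potential == 0.0:
        return np.zeros(domain.n_free)
    d = op.diag
    M = spla.LinearOperator(op.matrix.shape, matvec=lambda x: x / d)
    phi, info = spla.cg(op.matrix, rhs, rtol=rtol, atol=0.0, x0=x0,
                        maxiter=maxiter, M=M)
    if info != 0:
        res = np.linalg.norm(op.matrix @ phi - rhs) / np.linalg.norm(rhs)
        raise ElectricalSolveError(
            f"potential solve did not converge (info={info}, "
            f"relative residual {res:.2e})")
    return phi


def _boundary_values(domain: DiscreteDomain, v0: float) -> np.ndarray:
    bvals = np.zeros(domain.n_cells)
    bvals[domain.material == geo.ELECTRODE] = v0
    return bvals


def power_density(domain: DiscreteDomain, potential: np.ndarray,
                  conductivity: np.ndarray,
                  electrode_potential: float) -> ElectricalState:
    """Joule power density, total power and effective impedance.

    Power is accumulated per edge as ``g (dV)^2`` and split evenly between
    the edge's endpoint cells; the domain integral of the resulting density
    therefore equals the total dissipated power by construction.
    """
    op = DiffusionOperator(domain, conductivity)
    bvals = _boundary_values(domain, electrode_potential)
    e_ff, e_fd = op.edge_energies(potential, bvals)
    edges = domain.edges
    n = domain.n_free
    cell_power = (
        np.bincount(edges.ff_i, 0.5 * e_ff, minlength=n)
        + np.bincount(edges.ff_j, 0.5 * e_ff, minlength=n)
        + np.bincount(edges.fd_free, e_fd, minlength=n)
    )
    total = float(cell_power.sum())
    vol = domain.cell_volume_m3
    imp = (electrode_potential ** 2 / total) if total > 0 else np.inf
    return ElectricalState(
        potential=potential,
        power_density=cell_power / vol,
        total_power=total,
        electrode_potential=electrode_potential,
        effective_impedance=imp,
        conductivity=conductivity,
    )


def scale_to_recorded_power(state: ElectricalState,
                            target_power: float) -> ElectricalState:
    """Rescale a solved drive so total dissipated power equals the record."""
    if target_power < 0:
        raise ValueError("target power must be >= 0")
    if target_power == 0.0:
        return ElectricalState(
            potential=np.zeros_like(state.potential),
            power_density=np.zeros_like(state.power_density),
            total_power=0.0,
            electrode_potential=0.0,
            effective_impedance=state.effective_impedance,
            conductivity=state.conductivity,
        )
    if state.total_power <= 0:
        raise ElectricalSolveError(
            "cannot scale a zero-power solve to a positive target")
    return state.scaled(target_power / state.total_power)


def solve_drive(domain: DiscreteDomain, conductivity: np.ndarray, *,
                rtol: float = 1e-8,
                x0: Optional[np.ndarray] = None) -> ElectricalState:
    """Unit-potential solve packaged as an ElectricalState (V0 = 1).

    Assembles the conduction operator once and reuses it for both the
    potential solve and the power-density bookkeeping.
    """
    if len(domain.boundary_labels.get("ground", ())) == 0:
        raise ElectricalSolveError("scene has no ground boundary; system singular")
    if len(domain.boundary_labels.get("electrode_surface", ())) == 0:
        raise ElectricalSolveError("scene has no energised electrode cells")
    op = DiffusionOperator(domain, conductivity)
    bvals = _boundary_values(domain, 1.0)
    rhs = op.dirichlet_rhs(bvals)
    d = op.diag
    M = spla.LinearOperator(op.matrix.shape, matvec=lambda x: x / d)
    phi, info = spla.cg(op.matrix, rhs, rtol=rtol, atol=0.0, x0=x0,
                        maxiter=20000, M=M)
    if info != 0:
        raise ElectricalSolveError(f"potential solve did not converge (info={info})")
    return _state_from_operator(domain, op, phi, bvals, 1.0, conductivity)


def _state_from_operator(domain, op, potential, bvals, v0, conductivity):
    e_ff, e_fd = op.edge_energies(potential, bvals)
    edges = domain.edges
    n = domain.n_free
    cell_power = (
        np.bincount(edges.ff_i, 0.5 * e_ff, minlength=n)
        + np.bincount(edges.ff_j, 0.5 * e_ff, minlength=n)
        + np.bincount(edges.fd_free, e_fd, minlength=n)
    )
    total = float(cell_power.sum())
    imp = (v0 ** 2 / total) if total > 0 else np.inf
    return ElectricalState(
        potential=potential, power_density=cell_power / domain.cell_volume_m3,
        total_power=total, electrode_potential=v0,
        effective_impedance=imp, conductivity=conductivity)
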