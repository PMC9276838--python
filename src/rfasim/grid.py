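"""Cell-centred finite-volume discretisation of a Scene.

A :class:`DiscreteDomain` is a uniform cell-centred grid clipped to the
scene: cells classified ``OUTSIDE`` carry no unknowns, cells in Dirichlet
classes (``ELECTRODE``/``GROUND``) carry prescribed values, and the rest are
free.  Faces between free cells and Dirichlet cells may carry a sub-cell
fraction ``theta`` in (0, 1] locating the true boundary along the cell-to-
cell edge (a Shortley-Weller embedded boundary, computed by bisection on
the scene's signed-distance functions).  All sparse operators are built
from the edge lists stored on the domain, so the electrical and thermal
solvers share one discretisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp

from . import geometry as geo


class DiscretizationError(RuntimeError):
    pass


@dataclass
class EdgeSet:
    """Interior (free-free) and boundary (free-Dirichlet) edges of the grid.

    ``theta`` is the fractional distance from the free cell centre to the
    embedded boundary along the edge (1.0 when no SDF refinement applies).
    """

    ff_i: np.ndarray          # free-cell linear indices (compressed)
    ff_j: np.ndarray
    fd_free: np.ndarray       # compressed free index of the free endpoint
    fd_dir: np.ndarray        # full-grid linear index of the Dirichlet cell
    fd_theta: np.ndarray


@dataclass
class DiscreteDomain:
    origin: np.ndarray        # mm, position of cell (0,0,0) centre
    spacing: float            # mm, isotropic
    shape: tuple              # (nx, ny, nz) cells
    material: np.ndarray      # int8 per cell, flat, full grid
    free_mask: np.ndarray     # bool per cell, flat
    free_index: np.ndarray    # full -> compressed index (-1 outside)
    edges: EdgeSet
    boundary_labels: Dict[str, np.ndarray] = field(default_factory=dict)
    scene: Optional[geo.Scene] = None

    # -- basic queries ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_free(self) -> int:
        return int(self.free_mask.sum())

    @property
    def cell_volume_m3(self) -> float:
        return (self.spacing * 1e-3) ** 3

    def cell_centers(self, which: Optional[np.ndarray] = None) -> np.ndarray:
        """Physical centres (mm) of all cells or of given flat indices."""
        if which is None:
            which = np.arange(self.n_cells)
        idx = np.stack(np.unravel_index(which, self.shape), axis=1)
        return self.origin + idx * self.spacing

    def free_centers(self) -> np.ndarray:
        return self.cell_centers(np.flatnonzero(self.free_mask))

    def full_field(self, free_values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a free-cell vector onto the full (nx,ny,nz) grid."""
        out = np.full(self.n_cells, fill, dtype=float)
        out[self.free_mask] = free_values
        return out.reshape(self.shape)

    def material_grid(self) -> np.ndarray:
        return self.material.reshape(self.shape)


def discretize_scene(scene: geo.Scene, resolution: float,
                     pad_cells: int = 2) -> DiscreteDomain:
    """Rasterise a scene onto a uniform cell-centred grid.

    The grid covers the scene bounding box plus ``pad_cells`` cells of
    padding on every side (so Dirichlet layers just outside the medium, such
    as a return pad under a beaker, are representable).  Refining the
    resolution increases the cell count monotonically.
    """
    h = float(resolution)
    if h <= 0:
        raise DiscretizationError(f"resolution must be positive, got {h}")
    if scene.electrode is not None and h >= scene.electrode.nominal_diameter / 2:
        raise DiscretizationError(
            f"resolution {h} mm too coarse for a "
            f"{scene.electrode.nominal_diameter} mm electrode")

    lo = np.asarray(scene.bbox_min, float) - pad_cells * h
    hi = np.asarray(scene.bbox_max, float) + pad_cells * h
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / h)) for k in range(3))
    origin = lo + h / 2.0

    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    centers = origin + np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * h
    material = scene.material_at(centers).astype(np.int8)

    if scene.electrode is not None and not np.any(material == geo.ELECTRODE):
        raise DiscretizationError(
            f"resolution {h} mm resolves no electrode cells")

    dirichlet = (material == geo.ELECTRODE) | (material == geo.GROUND)
    free_mask = (material != geo.OUTSIDE) & ~dirichlet
    free_index = -np.ones(material.size, dtype=np.int64)
    free_index[free_mask] = np.arange(free_mask.sum())

    edges = _build_edges(shape, centers, material, free_mask, free_index,
                         scene, h)
    labels = _boundary_labels(shape, material, free_mask, scene)

    return DiscreteDomain(origin=origin, spacing=h, shape=shape,
                          material=material, free_mask=free_mask,
                          free_index=free_index, edges=edges,
                          boundary_labels=labels, scene=scene)


def _axis_neighbors(shape):
    """Pairs of flat indices of face-adjacent cells, per axis."""
    lin = np.arange(int(np.prod(shape))).reshape(shape)
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(0, -1)
        sl_hi[ax] = slice(1, None)
        yield lin[tuple(sl_lo)].ravel(), lin[tuple(sl_hi)].ravel()


def _build_edges(shape, centers, material, free_mask, free_index, scene, h):
    dirichlet = (material == geo.ELECTRODE) | (material == geo.GROUND)
    ff_i, ff_j = [], []
    fd_free, fd_dir, fd_theta = [], [], []
    for i_lo, i_hi in _axis_neighbors(shape):
        both_free = free_mask[i_lo] & free_mask[i_hi]
        ff_i.append(free_index[i_lo[both_free]])
        ff_j.append(free_index[i_hi[both_free]])
        for i_f, i_d in ((i_lo, i_hi), (i_hi, i_lo)):
            m = free_mask[i_f] & dirichlet[i_d]
            if not m.any():
                continue
            f_idx = i_f[m]
            d_idx = i_d[m]
            theta = _edge_theta(centers[f_idx], centers[d_idx],
                                material[d_idx], scene)
            fd_free.append(free_index[f_idx])
            fd_dir.append(d_idx)
            fd_theta.append(theta)

    cat = lambda parts: (np.concatenate(parts) if parts
                         else np.empty(0, dtype=np.int64))
    return EdgeSet(
        ff_i=cat(ff_i), ff_j=cat(ff_j),
        fd_free=cat(fd_free), fd_dir=cat(fd_dir),
        fd_theta=(np.concatenate(fd_theta) if fd_theta
                  else np.empty(0, dtype=float)),
    )


def _edge_theta(p_free, p_dir, mat_dir, scene, n_bisect=30, theta_min=0.05):
    """Fractional boundary location along free->Dirichlet edges.

    Bisects the relevant signed-distance function; edges whose Dirichlet
    class has no SDF keep theta = 1 (boundary at the neighbour centre).
    """
    theta = np.ones(len(p_free))
    for code, sdf in ((geo.ELECTRODE, scene.electrode_sdf),
                      (geo.GROUND, scene.ground_sdf)):
        if sdf is None:
            continue
        m = mat_dir == code
        if not m.any():
            continue
        a = p_free[m]
        b = p_dir[m]
        sf = sdf(a)
        sd = sdf(b)
        # only refine edges that actually cross the zero level
        crossing = (sf > 0) & (sd <= 0)
        t_lo = np.zeros(m.sum())
        t_hi = np.ones(m.sum())
        for _ in range(n_bisect):
            t_mid = 0.5 * (t_lo + t_hi)
            s_mid = sdf(a + t_mid[:, None] * (b - a))
            go_hi = s_mid > 0
            t_lo = np.where(go_hi, t_mid, t_lo)
            t_hi = np.where(go_hi, t_hi, t_mid)
        t = 0.5 * (t_lo + t_hi)
        t = np.where(crossing, t, 1.0)
        theta[m] = np.clip(t, theta_min, 1.0)
    return theta


def _boundary_labels(shape, material, free_mask, scene):
    """Named cell sets: electrode_surface, ground, vessel_wall, insulated_exterior."""
    labels = {
        "electrode_surface": np.flatnonzero(material == geo.ELECTRODE),
        "ground": np.flatnonzero(material == geo.GROUND),
    }
    # vessel_wall: free tissue cells adjacent to lumen cells
    wall = np.zeros(material.size, bool)
    lumen = material == geo.VESSEL_LUMEN
    if lumen.any():
        for i_lo, i_hi in _axis_neighbors(shape):
            wall[i_lo[(material[i_lo] == geo.TISSUE) & lumen[i_hi]]] = True
            wall[i_hi[(material[i_hi] == geo.TISSUE) & lumen[i_lo]]] = True
        labels["vessel_wall"] = np.flatnonzero(wall)
    # insulated exterior: free cells with at least one OUTSIDE or grid-edge face
    ext = np.zeros(material.size, bool)
    grid = np.zeros(shape, bool)
    grid[0, :, :] = grid[-1, :, :] = True
    grid[:, 0, :] = grid[:, -1, :] = True
    grid[:, :, 0] = grid[:, :, -1] = True
    ext |= grid.ravel() & free_mask
    outside = material == geo.OUTSIDE
    for i_lo, i_hi in _axis_neighbors(shape):
        ext[i_lo[free_mask[i_lo] & outside[i_hi]]] = True
        ext[i_hi[free_mask[i_hi] & outside[i_lo]]] = True
    labels["insulated_exterior"] = np.flatnonzero(ext)
    return labels


# ----------------------------------------------------------------------------
# operator assembly


class DiffusionOperator:
    """Sparse SPD diffusion/conduction operator on the free cells.

    For coefficient field ``k`` (per cell, SI units per metre, e.g. S/m or
    W/(m K)) the face conductance between adjacent free cells i, j is the
    harmonic mean ``h_m * 2 k_i k_j / (k_i + k_j)`` (exact for 1D series
    conduction); a face cut by an embedded Dirichlet boundary at fraction
    ``theta`` has conductance ``k_i h_m / theta``.  ``A @ u`` is in SI watts
    (or W/K-scaled) per cell; interior rows sum to zero (conservation).
    """

    def __init__(self, domain: DiscreteDomain, coeff_per_cell: np.ndarray,
                 include_boundary: bool = True):
        """``include_boundary=False`` drops the free-Dirichlet faces, i.e.
        the labelled boundaries become insulated (used by the thermal solver,
        where the electrical Dirichlet sets are not thermal boundaries)."""
        coeff = np.asarray(coeff_per_cell, float)
        if coeff.size == domain.n_cells:
            coeff_full = coeff
        elif coeff.size == domain.n_free:
            coeff_full = np.zeros(domain.n_cells)
            coeff_full[domain.free_mask] = coeff
        else:
            raise ValueError("coefficient field has wrong size")
        if np.any(coeff_full[domain.free_mask] <= 0):
            raise ValueError("diffusion coefficient must be positive on all cells")

        self.domain = domain
        h_m = domain.spacing * 1e-3
        e = domain.edges
        kf = coeff_full[domain.free_mask]

        ki = kf[e.ff_i]
        kj = kf[e.ff_j]
        self.g_ff = h_m * 2.0 * ki * kj / (ki + kj)

        # boundary faces: conduct from the free centre to the boundary point
        if include_boundary:
            self.g_fd = kf[e.fd_free] * h_m / e.fd_theta
        else:
            self.g_fd = np.zeros_like(e.fd_theta)

        n = domain.n_free
        diag = np.bincount(e.ff_i, self.g_ff, minlength=n) \
             + np.bincount(e.ff_j, self.g_ff, minlength=n) \
             + np.bincount(e.fd_free, self.g_fd, minlength=n)
        rows = np.concatenate([e.ff_i, e.ff_j, np.arange(n)])
        cols = np.concatenate([e.ff_j, e.ff_i, np.arange(n)])
        vals = np.concatenate([-self.g_ff, -self.g_ff, diag])
        self.matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.diag = diag

    def dirichlet_rhs(self, boundary_values: np.ndarray) -> np.ndarray:
        """RHS contribution for prescribed values on Dirichlet cells.

        ``boundary_values`` is a full-grid flat array (values only read at
        the Dirichlet cells referenced by boundary edges).
        """
        e = self.domain.edges
        return np.bincount(e.fd_free, self.g_fd * boundary_values[e.fd_dir],
                           minlength=self.domain.n_free)

    def edge_energies(self, u_free: np.ndarray,
                      boundary_values: np.ndarray):
        """Per-edge dissipation g * (du)^2, split into interior/boundary."""
        e = self.domain.edges
        du_ff = u_free[e.ff_i] - u_free[e.ff_j]
        du_fd = u_free[e.fd_free] - boundary_values[e.fd_dir]
        return self.g_ff * du_ff**2, self.g_fd * du_fd**2

    def boundary_fluxes(self, u_free: np.ndarray,
                        boundary_values: np.ndarray) -> np.ndarray:
        """Flux (W) out of the free domain through each boundary edge."""
        e = self.domain.edges
        return self.g_fd * (u_free[e.fd_free] - boundary_values[e.fd_dir])


def assemble_diffusion_operator(domain: DiscreteDomain,
                                coeff_per_cell: np.ndarray) -> DiffusionOperator:
    """Convenience wrapper; see :class:`DiffusionOperator`."""
    return DiffusionOperator(domain, coeff_per_cell)


# ----------------------------------------------------------------------------
# export


def export_vtk(domain: DiscreteDomain, path, fields: Optional[dict] = None):
    """Write the domain (and optional full-grid cell fields) as legacy VTK.

    Structured-points ASCII; loadable in ParaView for inspection.
    """
    nx, ny, nz = domain.shape
    fields = fields or {}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nrfasim domain\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = domain.origin
        f.write(f"ORIGIN {o[0]} {o[1]} {o[2]}\n")
        h = domain.spacing
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        mat = domain.material.reshape(domain.shape)
        _write_vtk_scalar(f, "material", mat)
        for name, arr in fields.items():
            _write_vtk_scalar(f, name, np.asarray(arr).reshape(domain.shape))


def _write_vtk_scalar(f, name, grid):
    f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    # VTK structured points vary x fastest
    flat = np.transpose(grid, (2, 1, 0)).ravel()
    np.savetxt(f, flat.reshape(-1, 1), fmt="%.6g")
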