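"""Simulation scenes for umbrella-electrode radiofrequency ablation.

Geometry lives in a right-handed millimetre frame.  In the electrode's own
frame the tip sits at the origin and the shaft axis points along -z (the
direction of insertion); the shaft body extends toward +z.  Image volumes use
0-based voxel indices with physical position = origin + index * spacing.

A :class:`Scene` is a purely geometric description: it can classify any point
into a material class and expose signed-distance functions for the energised
electrode surface and the return (ground) boundary.  Discretisation onto a
grid happens in :mod:`rfasim.grid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

# material class codes used on grids and in Scene.material_at
OUTSIDE = 0     # not part of the conductive/thermal domain
TISSUE = 1      # agar or liver parenchyma
VESSEL_LUMEN = 2
ELECTRODE = 3   # energised metal (tines + exposed tip)
SHAFT = 4       # insulated introducer shaft (metal, not energised)
GROUND = 5      # return-pad region (electrical Dirichlet 0)

MATERIAL_NAMES = {
    OUTSIDE: "outside",
    TISSUE: "tissue",
    VESSEL_LUMEN: "vessel_lumen",
    ELECTRODE: "electrode",
    SHAFT: "shaft",
    GROUND: "ground",
}


class GeometryError(ValueError):
    """Raised for inconsistent or out-of-range geometric parameters."""


@dataclass(frozen=True)
class ElectrodeSpec:
    """Umbrella (LeVeen-style) multi-tine electrode.

    ``tine_paths`` are polylines in mm, each starting at ``tip_position``.
    The ideal tine is a circular arc lying in a plane through the shaft
    axis; deployment is modelled as a similarity scaling about the tip, so
    the maximum radial extent is ``deployed_fraction * nominal_diameter/2``.
    """

    nominal_diameter: float            # mm, 20-40 family
    n_tines: int
    shaft_axis: np.ndarray             # unit vector, direction of insertion
    tip_position: np.ndarray           # mm
    tine_paths: tuple                  # tuple of (k,3) float arrays, mm
    deployed_fraction: float = 1.0
    wire_radius: float = 0.4           # mm, tine wire radius (sub-grid)
    shaft_length: float = 120.0        # mm of insulated shaft behind the tip

    def max_radial_extent(self) -> float:
        """Largest distance of any tine point from the shaft axis (mm)."""
        axis = self.shaft_axis / np.linalg.norm(self.shaft_axis)
        best = 0.0
        for path in self.tine_paths:
            rel = path - self.tip_position
            axial = rel @ axis
            radial = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
            best = max(best, float(radial.max()))
        return best

    def all_tine_points(self) -> np.ndarray:
        return np.vstack(self.tine_paths)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ElectrodeSpec":
        """Apply a rigid transform (rotation then translation) to the spec."""
        paths = tuple((p @ rotation.T) + translation for p in self.tine_paths)
        return replace(
            self,
            shaft_axis=rotation @ self.shaft_axis,
            tip_position=rotation @ self.tip_position + translation,
            tine_paths=paths,
        )


@dataclass(frozen=True)
class VesselSpec:
    """Straight or polyline vessel with plug flow.

    ``flow_speed`` is the mean lumen velocity in mm/s (the bench experiments
    used 105 mm/s water flow in a 5 mm channel); ``fluid_temperature`` is the
    temperature of the incoming fluid in deg C (room-temperature water for
    phantoms, arterial blood in vivo).
    """

    centerline: np.ndarray             # (k,3) mm
    diameter: float = 5.0              # mm
    flow_speed: float = 105.0          # mm/s
    fluid_temperature: float = 20.0    # deg C

    def __post_init__(self):
        if self.diameter <= 0:
            raise GeometryError(f"vessel diameter must be positive, got {self.diameter}")
        if self.flow_speed < 0:
            raise GeometryError(f"vessel flow speed must be >= 0, got {self.flow_speed}")
        object.__setattr__(self, "centerline", np.asarray(self.centerline, float))

    def distance_to_centerline(self, points: np.ndarray) -> np.ndarray:
        return _polyline_distance(points, self.centerline)


@dataclass(frozen=True)
class PhantomSpec:
    """Agar-filled cylindrical beaker with a return pad on its bottom.

    Defaults describe a two-litre beaker (radius 62 mm, fill height 166 mm,
    pi * 62^2 * 166 mm^3 ~= 2.0 L).
    """

    beaker_radius: float = 62.0        # mm
    beaker_height: float = 166.0       # mm (agar fill height)
    pad_radius: Optional[float] = None  # mm; None -> whole bottom is the pad
    vessel: Optional[VesselSpec] = None

    def __post_init__(self):
        if self.beaker_radius <= 0 or self.beaker_height <= 0:
            raise GeometryError("beaker dimensions must be positive")

    @property
    def volume_litres(self) -> float:
        return np.pi * self.beaker_radius**2 * self.beaker_height * 1e-6


@dataclass
class Scene:
    """Geometric world ready for discretisation.

    ``material_at(points)`` maps (n,3) mm points to material codes; exactly
    one code per point (the classes partition space).  ``electrode_sdf`` and
    ``ground_sdf`` are optional signed-distance functions (negative inside
    the Dirichlet region) used for sub-cell boundary placement; when absent
    the staircase cell labelling alone defines the boundary.
    """

    electrode: Optional[ElectrodeSpec]
    bbox_min: np.ndarray               # mm, axis-aligned bounds of the medium
    bbox_max: np.ndarray
    material_at: Callable[[np.ndarray], np.ndarray]
    vessels: list = field(default_factory=list)
    electrode_sdf: Optional[Callable[[np.ndarray], np.ndarray]] = None
    ground_sdf: Optional[Callable[[np.ndarray], np.ndarray]] = None
    description: dict = field(default_factory=dict)
    initial_temperature: float = 20.0  # deg C

    def classify(self, points: np.ndarray) -> np.ndarray:
        return self.material_at(np.atleast_2d(np.asarray(points, float)))


# ----------------------------------------------------------------------------
# electrode construction


def build_leveen_electrode(
    nominal_diameter: float,
    n_tines: int,
    deployed_fraction: float = 1.0,
    *,
    tip_position: Sequence[float] = (0.0, 0.0, 0.0),
    shaft_axis: Sequence[float] = (0.0, 0.0, -1.0),
    arc_angle_deg: float = 160.0,
    points_per_tine: int = 40,
) -> ElectrodeSpec:
    """Ideal umbrella electrode with circular-arc tines.

    Each tine leaves the tip tangent to the insertion direction and curves
    back toward the shaft in its azimuthal plane; tines are equally spaced
    in azimuth.  At ``deployed_fraction = 1`` the maximum radial extent of
    the tines equals ``nominal_diameter / 2``; partial deployment scales the
    whole arc about the tip.

    Parameters
    ----------
    nominal_diameter : float
        Device family size in mm (20-40 supported).
    n_tines : int
        Number of tines (>= 4).
    deployed_fraction : float
        Fraction of full deployment in (0, 1].
    arc_angle_deg : float
        Turning angle of the full tine arc.  The vendor curve is
        proprietary; the default gives an umbrella whose tines end curving
        back toward the shaft.
    """
    if not (20.0 <= nominal_diameter <= 40.0):
        raise GeometryError(
            f"nominal_diameter must be in [20, 40] mm, got {nominal_diameter}")
    if n_tines < 4:
        raise GeometryError(f"n_tines must be >= 4, got {n_tines}")
    if not (0.0 < deployed_fraction <= 1.0):
        raise GeometryError(
            f"deployed_fraction must be in (0, 1], got {deployed_fraction}")

    tip = np.asarray(tip_position, float)
    axis = np.asarray(shaft_axis, float)
    axis = axis / np.linalg.norm(axis)

    phi_max = np.radians(arc_angle_deg)
    # arc radius so that max radial extent (1 - cos(phi)) * rho equals D/2
    extent_factor = 1.0 - np.cos(phi_max) if phi_max <= np.pi else 2.0
    rho = (nominal_diameter / 2.0) / extent_factor

    # orthonormal frame (u, v, w=axis)
    u, v = _orthonormal_basis(axis)

    phis = np.linspace(0.0, phi_max, points_per_tine)
    radial = rho * (1.0 - np.cos(phis)) * deployed_fraction
    axial = rho * np.sin(phis) * deployed_fraction     # along insertion dir

    paths = []
    for k in range(n_tines):
        az = 2.0 * np.pi * k / n_tines
        r_dir = np.cos(az) * u + np.sin(az) * v
        pts = tip[None, :] + np.outer(axial, axis) + np.outer(radial, r_dir)
        paths.append(pts)
    return ElectrodeSpec(
        nominal_diameter=nominal_diameter,
        n_tines=n_tines,
        shaft_axis=axis,
        tip_position=tip,
        tine_paths=tuple(paths),
        deployed_fraction=deployed_fraction,
    )


def _orthonormal_basis(w: np.ndarray):
    """Two unit vectors orthogonal to w (and each other)."""
    a = np.array([1.0, 0.0, 0.0])
    if abs(w @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(w, a)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v


def _polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to a polyline (exact point-segment)."""
    points = np.atleast_2d(points)
    a = poly[:-1]
    b = poly[1:]
    if len(a) == 0:
        return np.linalg.norm(points - poly[0], axis=1)
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    best = np.full(len(points), np.inf)
    for ai, abi, di in zip(a, ab, denom):
        t = np.clip(((points - ai) @ abi) / di, 0.0, 1.0)
        proj = ai + t[:, None] * abi
        d = np.linalg.norm(points - proj, axis=1)
        np.minimum(best, d, out=best)
    return best


# ----------------------------------------------------------------------------
# phantom scene


def build_phantom_scene(
    phantom: PhantomSpec,
    electrode: ElectrodeSpec,
    vessel_offset: Optional[float] = None,
    *,
    vessel: Optional[VesselSpec] = None,
    tip_depth: Optional[float] = None,
    initial_temperature: float = 20.0,
) -> Scene:
    """Beaker phantom with the electrode on the beaker axis.

    The electrode is inserted downward along the beaker axis with its tip at
    ``tip_depth`` above the bottom (default: mid-height).  ``vessel_offset``
    places a straight vertical channel at that distance from the shaft axis,
    measured to the channel *centerline* (configurable convention: pass a
    ``VesselSpec`` positioned by hand for anything else).  The return pad
    covers the beaker bottom.
    """
    R, H = phantom.beaker_radius, phantom.beaker_height
    if tip_depth is None:
        tip_depth = H / 2.0
    # place in beaker frame: bottom at z=0, axis = z
    tip = np.array([0.0, 0.0, tip_depth])
    elec = replace(
        electrode,
        tip_position=tip,
        shaft_axis=np.array([0.0, 0.0, -1.0]),
        tine_paths=tuple(p - electrode.tip_position + tip for p in electrode.tine_paths),
    )

    vspec = phantom.vessel if vessel is None else vessel
    if vessel_offset is not None:
        if vessel_offset + 2.5 >= R:
            raise GeometryError(
                f"vessel at offset {vessel_offset} mm does not fit inside "
                f"beaker of radius {R} mm")
        base = vspec if vspec is not None else VesselSpec(
            centerline=np.zeros((2, 3)), fluid_temperature=initial_temperature)
        vspec = replace(
            base,
            centerline=np.array([[vessel_offset, 0.0, -1.0],
                                 [vessel_offset, 0.0, H + 1.0]]),
        )
    if vspec is not None:
        d_axis = np.hypot(vspec.centerline[:, 0], vspec.centerline[:, 1]).max()
        if d_axis + vspec.diameter / 2.0 >= R:
            raise GeometryError("vessel channel lies outside the beaker")

    pad_r = phantom.pad_radius if phantom.pad_radius is not None else R
    tine_pts = elec.all_tine_points()
    tine_tree = cKDTree(_densify_polylines(elec.tine_paths, 0.25))
    shaft_a = tip
    shaft_b = tip - elec.shaft_axis * elec.shaft_length   # toward +z
    shaft_r = 1.25  # mm, introducer radius

    if np.hypot(tine_pts[:, 0], tine_pts[:, 1]).max() >= R:
        raise GeometryError("electrode tines extend outside the beaker")

    def material_at(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        r_ax = np.hypot(points[:, 0], points[:, 1])
        inside = (r_ax <= R) & (points[:, 2] >= 0.0) & (points[:, 2] <= H)
        out = np.full(len(points), OUTSIDE, dtype=np.int8)
        out[inside] = TISSUE
        # ground layer: below the bottom, within the pad radius
        below = (points[:, 2] < 0.0) & (r_ax <= pad_r)
        out[below] = GROUND
        if vspec is not None:
            dv = vspec.distance_to_centerline(points)
            out[inside & (dv <= vspec.diameter / 2.0)] = VESSEL_LUMEN
        # shaft cylinder (insulated)
        d_shaft = _segment_distance(points, shaft_a, shaft_b)
        out[inside & (d_shaft <= shaft_r)] = SHAFT
        # tines: within wire radius of any tine polyline (electrode wins)
        d_tine, _ = tine_tree.query(points, k=1)
        out[inside & (d_tine <= max(elec.wire_radius, 1e-9))] = ELECTRODE
        return out

    def ground_sdf(points: np.ndarray) -> np.ndarray:
        # negative below the bottom plane (inside the pad Dirichlet region)
        return np.atleast_2d(points)[:, 2]

    vessels = [vspec] if vspec is not None else []
    scene = Scene(
        electrode=elec,
        bbox_min=np.array([-R, -R, 0.0]),
        bbox_max=np.array([R, R, H]),
        material_at=material_at,
        vessels=vessels,
        electrode_sdf=None,     # thin tines: sub-grid, labelled by proximity
        ground_sdf=ground_sdf,
        description={
            "kind": "phantom",
            "beaker_radius": R,
            "beaker_height": H,
            "vessel_offset": vessel_offset,
            "electrode_diameter": elec.nominal_diameter,
        },
        initial_temperature=initial_temperature,
    )
    return scene


def _segment_distance(points, a, b):
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _densify_polylines(paths, step):
    """Resample polylines so consecutive samples are ~step mm apart."""
    out = []
    for p in paths:
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(np.ceil(s[-1] / step)) + 1, 2)
        si = np.linspace(0.0, s[-1], n)
        out.append(np.column_stack([np.interp(si, s, p[:, k]) for k in range(3)]))
    return np.vstack(out)


# ----------------------------------------------------------------------------
# analytic scenes (used by solver benchmarks; fixtures wrap these)


def build_concentric_sphere_scene(
    inner_radius: float,
    outer_radius: float,
    *,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> Scene:
    """Spherical electrode of radius a inside a grounded sphere of radius b.

    The classic spreading-resistance geometry: exact potential
    ``V(r) = V0 * (a/r) * (b - r)/(b - a)`` and total resistance
    ``(1/(4 pi sigma)) * (1/a - 1/b)``.
    """
    a, b = float(inner_radius), float(outer_radius)
    if not (0 < a < b):
        raise GeometryError("need 0 < inner_radius < outer_radius")
    c = np.asarray(center, float)

    def material_at(points):
        r = np.linalg.norm(np.atleast_2d(points) - c, axis=1)
        out = np.full(len(r), TISSUE, dtype=np.int8)
        out[r <= a] = ELECTRODE
        out[r >= b] = GROUND
        return out

    def electrode_sdf(points):
        return np.linalg.norm(np.atleast_2d(points) - c, axis=1) - a

    def ground_sdf(points):
        return b - np.linalg.norm(np.atleast_2d(points) - c, axis=1)

    return Scene(
        electrode=None,
        bbox_min=c - b,
        bbox_max=c + b,
        material_at=material_at,
        electrode_sdf=electrode_sdf,
        ground_sdf=ground_sdf,
        description={"kind": "concentric_spheres", "a": a, "b": b},
    )


def build_box_scene(
    size: Sequence[float],
    *,
    dirichlet_axis: Optional[int] = None,
    initial_temperature: float = 20.0,
) -> Scene:
    """Axis-aligned tissue box, optionally with opposite Dirichlet faces.

    With ``dirichlet_axis=k`` the low face along axis k becomes the
    energised boundary and the high face the ground, giving the 1D series
    conduction benchmark; otherwise all faces are insulated.
    """
    size = np.asarray(size, float)
    lo = np.zeros(3)
    hi = size

    def material_at(points):
        points = np.atleast_2d(points)
        out = np.full(len(points), TISSUE, dtype=np.int8)
        outside = np.any((points < lo) | (points > hi), axis=1)
        out[outside] = OUTSIDE
        if dirichlet_axis is not None:
            k = dirichlet_axis
            inside_others = np.ones(len(points), bool)
            for j in range(3):
                if j != k:
                    inside_others &= (points[:, j] >= lo[j]) & (points[:, j] <= hi[j])
            out[inside_others & (points[:, k] < lo[k])] = ELECTRODE
            out[inside_others & (points[:, k] > hi[k])] = GROUND
        return out

    electrode_sdf = ground_sdf = None
    if dirichlet_axis is not None:
        k = dirichlet_axis

        def electrode_sdf(points):
            return np.atleast_2d(points)[:, k] - lo[k]

        def ground_sdf(points):
            return hi[k] - np.atleast_2d(points)[:, k]

    return Scene(
        electrode=None,
        bbox_min=lo,
        bbox_max=hi,
        material_at=material_at,
        electrode_sdf=electrode_sdf,
        ground_sdf=ground_sdf,
        description={"kind": "box", "size": size.tolist(),
                     "dirichlet_axis": dirichlet_axis},
        initial_temperature=initial_temperature,
    )
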