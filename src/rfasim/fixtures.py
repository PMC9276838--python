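"""Synthetic inputs with known ground truth for every pipeline stage.

Everything the pipeline consumes in the lab — phantom scenes, generator
power logs, scanned slice images, CT volumes with deployed tines — has a
deterministic, seeded emulator here, so the full chain can be exercised
end-to-end with analytically known answers.  Same recipe + same seed gives
bit-identical output.

The phantom recipe mirrors the bench geometry: a two-litre beaker with a
return pad on its bottom, a 4 cm umbrella electrode on the beaker axis,
optionally a straight vertical 5 mm water channel at 25/30/35 mm from the
shaft, carrying 10.5 cm/s room-temperature water.  The generator emulation
is a ramp to a plateau (a 5-minute ablation by default); the vendor's
impedance-control loop is deliberately not modelled — the recorded power is
the simulation's input, as in the validation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import ndimage

from . import geometry as geo
from .electrical import PowerTrace


class FixtureError(ValueError):
    pass


# ----------------------------------------------------------------------------
# analytic scenes with closed-form truth


@dataclass
class AnalyticScene:
    scene: geo.Scene
    truth: Callable
    meta: dict


def make_analytic_scene(kind: str, **params) -> AnalyticScene:
    """Scene plus closed-form solution handle for solver benchmarks.

    Kinds
    -----
    ``concentric_spheres(a, b, sigma, v0)``
        truth(r) = potential at radius r; meta carries the exact spreading
        resistance ``(1/(4 pi sigma)) (1/a - 1/b)`` in ohms.
    ``perfused_box(q, props...)``
        truth(t) = uniform temperature under uniform volumetric heating q
        (W/m^3) with perfusion only: exponential relaxation to
        ``T_a + q / (w rho_b c_b)`` with time constant
        ``rho c / (w rho_b c_b)``.
    ``slab(k1, k2, t_hot, t_cold, length)``
        two-material series slab; truth(x) = steady profile, meta carries
        the interface flux from the harmonic-mean closed form.
    """
    if kind == "concentric_spheres":
        a = params.get("a", 1.0)
        b = params.get("b", 60.0)
        sigma = params.get("sigma", 0.333)
        v0 = params.get("v0", 1.0)
        scene = geo.build_concentric_sphere_scene(a, b)

        def truth(r):
            r = np.asarray(r, float)
            return v0 * (a / r) * (b - r) / (b - a)

        resistance = (1.0 / (4 * np.pi * sigma)) * (1 / a - 1 / b) * 1e3  # ohm
        return AnalyticScene(scene, truth, {
            "a": a, "b": b, "sigma": sigma, "v0": v0,
            "resistance_ohm": resistance,
            "resistance_infinite_ohm": 1e3 / (4 * np.pi * sigma * a),
        })

    if kind == "perfused_box":
        from .thermal import ThermalProperties
        q = params.get("q", 5.0e4)           # W/m^3
        props = params.get("props", ThermalProperties())
        size = params.get("size", (20.0, 20.0, 20.0))
        t0 = params.get("t0", props.arterial_temperature)
        scene = geo.build_box_scene(size, initial_temperature=t0)
        wcb = props.perfusion_rate * props.blood_density * props.blood_specific_heat
        if wcb <= 0:
            raise FixtureError("perfused_box needs a positive perfusion rate")
        tau = props.density * props.specific_heat / wcb
        t_inf = props.arterial_temperature + q / wcb

        def truth(t):
            t = np.asarray(t, float)
            return t_inf + (t0 - t_inf) * np.exp(-t / tau)

        return AnalyticScene(scene, truth, {
            "q": q, "tau_s": tau, "t_inf": t_inf, "props": props})

    if kind == "slab":
        k1 = params.get("k1", 0.5)
        k2 = params.get("k2", 2.0)
        t_hot = params.get("t_hot", 80.0)
        t_cold = params.get("t_cold", 20.0)
        length = params.get("length", 20.0)     # mm per layer
        width = params.get("width", 8.0)
        scene = geo.build_box_scene((2 * length, width, width),
                                    dirichlet_axis=0)
        base_material = scene.material_at

        def material_at(points):
            return base_material(points)

        # harmonic-mean series flux per unit area (W/m^2)
        L = length * 1e-3
        flux = (t_hot - t_cold) / (L / k1 + L / k2)
        x_if = length

        def truth(x_mm):
            x = np.asarray(x_mm, float)
            t_mid = t_hot - flux * (L / k1)
            left = t_hot + (t_mid - t_hot) * (x / length)
            right = t_mid + (t_cold - t_mid) * ((x - length) / length)
            return np.where(x <= x_if, left, right)

        return AnalyticScene(scene, truth, {
            "k1": k1, "k2": k2, "t_hot": t_hot, "t_cold": t_cold,
            "length_mm": length, "flux_W_m2": flux})

    raise FixtureError(f"unknown analytic scene kind {kind!r}")


# ----------------------------------------------------------------------------
# phantom fixture (scene + power trace)


def make_power_trace(duration_s: float = 300.0, plateau_W: float = 90.0, *,
                     ramp_s: float = 30.0, rolloff_at_s: Optional[float] = None,
                     noise_sd: float = 0.0, seed: int = 0) -> PowerTrace:
    """Generator-log emulation: linear ramp to a plateau at 1 Hz.

    ``rolloff_at_s`` inserts an impedance-rise power dip (to 10% for 15 s)
    at the given time, mimicking the generator backing off near tissue
    desiccation; by default the plateau is clean.
    """
    t = np.arange(0.0, duration_s + 0.5)
    p = np.minimum(t / max(ramp_s, 1e-9), 1.0) * plateau_W
    if rolloff_at_s is not None:
        dip = (t >= rolloff_at_s) & (t < rolloff_at_s + 15.0)
        p[dip] *= 0.1
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        p = np.maximum(p + rng.normal(0.0, noise_sd, p.size), 0.0)
    return PowerTrace(timestamps=t, applied_power=p)


def make_phantom_fixture(vessel_offset: Optional[float] = None, *,
                         seed: int = 0,
                         electrode_diameter: float = 40.0,
                         n_tines: int = 10,
                         duration_s: float = 300.0,
                         plateau_W: float = 90.0,
                         noise_sd: float = 0.0) -> Tuple[geo.Scene, PowerTrace]:
    """Bench-experiment emulation: beaker scene + deterministic power log.

    ``vessel_offset`` of None reproduces the no-vessel layout; 25/30/35 mm
    are the offsets used to probe the heat-sink effect (5 mm channel,
    10.5 cm/s water at room temperature).
    """
    electrode = geo.build_leveen_electrode(electrode_diameter, n_tines, 1.0)
    phantom = geo.PhantomSpec()
    scene = geo.build_phantom_scene(phantom, electrode,
                                    vessel_offset=vessel_offset)
    trace = make_power_trace(duration_s, plateau_W, noise_sd=noise_sd,
                             seed=seed)
    return scene, trace


# ----------------------------------------------------------------------------
# slice images with known boundaries


def disc_contour(radius: float, center=(0.0, 0.0), n: int = 720) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def disc_with_bite_contour(radius: float, bite_radius: float,
                           bite_center_offset: float,
                           center=(0.0, 0.0), n: int = 1440) -> np.ndarray:
    """Disc with a circular 'bite' removed from its +x side.

    Emulates the heat-sink indentation a flow channel leaves in an axial
    phantom section.  The bite circle is centred ``bite_center_offset`` from
    the disc centre along +x.
    """
    pts = disc_contour(radius, center, n)
    bc = np.array([center[0] + bite_center_offset, center[1]])
    d = np.linalg.norm(pts - bc, axis=1)
    keep = d >= bite_radius
    # replace removed arc with the bite circle's arc (the part inside disc)
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    bite_pts = np.column_stack([bc[0] + bite_radius * np.cos(th),
                                bc[1] + bite_radius * np.sin(th)])
    inside = np.linalg.norm(bite_pts - np.asarray(center), axis=1) <= radius
    boundary = np.vstack([pts[keep], bite_pts[inside]])
    # order by angle around the region centroid to get a simple closed loop
    centroid = boundary.mean(axis=0)
    ang = np.arctan2(boundary[:, 1] - centroid[1], boundary[:, 0] - centroid[0])
    return boundary[np.argsort(ang)]


def make_slice_image(boundary: np.ndarray, *, pixel_spacing: float = 0.2,
                     noise_sd: float = 0.05, blur_px: float = 1.0,
                     margin_mm: float = 5.0, contrast: float = 0.5,
                     background: float = 0.25, seed: int = 0):
    """Rasterise a closed contour into a noisy grayscale scan.

    Returns ``(SliceScan, truth_contour_mm)`` where the truth contour is in
    the image's mm frame (origin at pixel (0, 0) centre).  Interior is
    brighter by ``contrast``; Gaussian noise and a mild blur emulate the
    flat-bed scan.
    """
    from .segmentation import SliceScan

    b = np.asarray(boundary, float)
    lo = b.min(axis=0) - margin_mm
    hi = b.max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / pixel_spacing).astype(int)[::-1]  # rows, cols
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    px_mm = np.column_stack([xx.ravel(), yy.ravel()]) * pixel_spacing + lo
    inside = _points_in_polygon(px_mm, b).reshape(shape)
    img = background + contrast * inside.astype(float)
    if blur_px > 0:
        img = ndimage.gaussian_filter(img, blur_px)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    truth = b - lo
    return SliceScan(image=img, pixel_spacing=pixel_spacing), truth


def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd rule point-in-polygon, vectorised over points."""
    x, y = points[:, 0], points[:, 1]
    n = len(poly)
    inside = np.zeros(len(points), bool)
    x0, y0 = poly[-1]
    for x1, y1 in poly:
        cross = ((y0 > y) != (y1 > y))
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = (x1 - x0) * (y - y0) / (y1 - y0) + x0
        inside ^= cross & (x < xin)
        x0, y0 = x1, y1
    return inside


# ----------------------------------------------------------------------------
# CT-like tine volumes


def make_tine_ct(electrode: geo.ElectrodeSpec, deflections_mm, *,
                 voxel: float = 0.8, margin_mm: float = 8.0,
                 metal_intensity: float = 3000.0, background: float = 40.0,
                 noise_sd: float = 10.0, seed: int = 0):
    """CT-like volume with metal-density tine curves painted in.

    ``deflections_mm`` gives one in-plane tilt per tine: the tine is bent
    within its own azimuthal plane so its distal end moves by the given
    distance (ramped linearly along the arc), emulating tines deflected by
    tissue heterogeneity.  Returns ``(volume, spacing, origin_mm,
    truth_paths)``; truth paths are the deflected centerlines in mm.
    """
    deflections = np.asarray(deflections_mm, float)
    if deflections.size != electrode.n_tines:
        raise FixtureError(
            f"need one deflection per tine ({electrode.n_tines}), "
            f"got {deflections.size}")

    truth = []
    axis = electrode.shaft_axis
    tip = electrode.tip_position
    for path, defl in zip(electrode.tine_paths, deflections):
        truth.append(_deflect_in_plane(np.asarray(path), tip, axis, defl))

    all_pts = np.vstack(truth)
    lo = all_pts.min(axis=0) - margin_mm
    hi = all_pts.max(axis=0) + margin_mm
    shape = np.ceil((hi - lo) / voxel).astype(int)
    for p in truth:
        if np.any(p < lo + voxel) or np.any(p > hi - voxel):
            raise FixtureError("deflected tine leaves the volume")

    rng = np.random.default_rng(seed)
    vol = rng.normal(background, noise_sd, tuple(shape))
    # paint tines: mark voxels within ~1 voxel of densified centerlines
    dense = geo._densify_polylines(truth, voxel / 3.0)
    idx = np.round((dense - lo) / voxel).astype(int)
    idx = np.clip(idx, 0, shape - 1)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = metal_intensity
    # thicken by one dilation so the wire is > 1 voxel wide
    metal = vol >= metal_intensity
    metal = ndimage.binary_dilation(metal, iterations=1)
    vol[metal] = metal_intensity
    return vol, float(voxel), lo, truth


def _deflect_in_plane(path, tip, axis, deflection):
    """Tilt a tine in its azimuthal plane so the distal end moves by
    ``deflection`` mm, ramping linearly with arc length from the tip."""
    if deflection == 0.0:
        return path.copy()
    rel = path - tip
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_frac = s / s[-1] if s[-1] > 0 else s
    # in-plane direction orthogonal to the local radial direction: rotate
    # about the azimuthal normal n = axis x r_dir
    end_rel = rel[-1]
    r_dir = end_rel - (end_rel @ axis) * axis
    r_norm = np.linalg.norm(r_dir)
    if r_norm < 1e-9:
        raise FixtureError("cannot deflect a tine lying on the shaft axis")
    r_dir /= r_norm
    n = np.cross(axis, r_dir)
    angle = deflection / np.linalg.norm(end_rel)
    out = np.empty_like(path)
    for i, (p, f) in enumerate(zip(rel, s_frac)):
        a = angle * f
        out[i] = tip + _rotate_about(p, n, a)
    return out


def _rotate_about(v, axis, angle):
    axis = axis / np.linalg.norm(axis)
    return (v * np.cos(angle) + np.cross(axis, v) * np.sin(angle)
            + axis * (axis @ v) * (1 - np.cos(angle)))
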