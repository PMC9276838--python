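"""Equidistant sampling, surface-distance errors, chart model, paired test."""

import numpy as np
import pytest
import trimesh
from scipy.spatial import cKDTree

from rfasim.fixtures import disc_contour
from rfasim.metrics import (DegenerateComparisonError, MetricsError,
                            build_chart_model, paired_comparison,
                            sample_equidistant, surface_error)
from rfasim.registration import RigidTransform


def brute_force_mesh_distance(points, mesh):
    """Independent oracle: scalar point-to-triangle over all triangles."""
    tris = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for tri in tris:
            best = min(best, _point_triangle(p, tri))
        out[i] = best
    return out


def _point_triangle(p, tri):
    # Ericson-style closest point on triangle, scalar
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return np.linalg.norm(p - a)
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return np.linalg.norm(p - b)
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        v = d1 / (d1 - d3)
        return np.linalg.norm(p - (a + v * ab))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return np.linalg.norm(p - c)
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        w = d2 / (d2 - d6)
        return np.linalg.norm(p - (a + w * ac))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return np.linalg.norm(p - (b + w * (c - b)))
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return np.linalg.norm(p - (a + ab * v + ac * w))


class TestSampleEquidistant:
    def test_circle_64_points_exact_spacing(self):
        contour = disc_contour(10.0, n=4096)
        pts = sample_equidistant(contour, 64)
        assert len(pts) == 64
        gaps = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0),
                              axis=1)
        # equal arc-length spacing: every gap equals perimeter / 64
        assert gaps.std() / gaps.mean() < 1e-6
        # chords of equal arcs: mean chord = arc * sinc correction ~ 4e-4
        assert gaps.mean() == pytest.approx(2 * np.pi * 10.0 / 64, rel=1e-3)

    def test_three_points_on_circle_are_equilateral(self):
        pts = sample_equidistant(disc_contour(5.0, n=3000), 3)
        d = [np.linalg.norm(pts[i] - pts[(i + 1) % 3]) for i in range(3)]
        np.testing.assert_allclose(d, d[0], rtol=1e-5)

    def test_sphere_sampling_statistics(self):
        """~10,000 points on the unit sphere: count within 1%, mean NN
        spacing within 15% of sqrt(4 pi / n), spacing CV <= 10%."""
        sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        pts = sample_equidistant(sph, 10000, seed=0)
        assert abs(len(pts) - 10000) <= 100
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1]
        target = np.sqrt(4 * np.pi / 10000)
        assert abs(nn.mean() - target) / target < 0.15
        assert nn.std() / nn.mean() <= 0.10
        # points lie on the surface
        assert np.abs(np.linalg.norm(pts, axis=1) - 1.0).max() < 5e-3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(MetricsError):
            sample_equidistant(np.zeros((2, 2)), 64)
        with pytest.raises(MetricsError):
            sample_equidistant(disc_contour(5.0), 2)


class TestSurfaceError:
    def test_concentric_spheres_mean_equals_max_equals_gap(self):
        inner = trimesh.creation.icosphere(subdivisions=5, radius=20.0)
        outer = trimesh.creation.icosphere(subdivisions=5, radius=23.0)
        pts = sample_equidistant(inner, 1500, seed=2)
        rep = surface_error(pts, outer)
        assert rep.mean_error == pytest.approx(3.0, abs=0.01)
        assert rep.max_error == pytest.approx(3.0, abs=0.01)
        assert rep.max_error - rep.mean_error < 0.01

    def test_identical_surface_zero_error(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        rep = surface_error(mesh.vertices, mesh)
        assert rep.max_error < 1e-12

    def test_matches_brute_force_oracle(self, rng):
        """KD-pruned exact distances equal the all-triangles scan."""
        blob = trimesh.creation.icosphere(subdivisions=2, radius=10.0)
        blob = blob.copy()
        blob.vertices += rng.normal(0, 0.5, blob.vertices.shape)
        pts = rng.uniform(-15, 15, (80, 3))
        rep = surface_error(pts, blob)
        oracle = brute_force_mesh_distance(pts, blob)
        np.testing.assert_allclose(rep.distances, oracle, atol=1e-9)

    def test_rigid_invariance(self, rng):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
        pts = rng.uniform(-12, 12, (60, 3))
        rep0 = surface_error(pts, mesh)
        x = RigidTransform.from_axis_angle([1, 1, 0], 0.9, [5, -2, 11])
        mesh2 = mesh.copy()
        mesh2.apply_transform(x.matrix)
        rep1 = surface_error(x.apply(pts), mesh2)
        np.testing.assert_allclose(rep1.distances, rep0.distances, atol=1e-9)

    def test_direction_recorded_and_asymmetric(self):
        rep = surface_error(np.zeros((1, 3)),
                            trimesh.creation.icosphere(1, radius=5.0),
                            direction="true_to_model")
        assert rep.direction == "true_to_model"

    def test_2d_contour_distances(self):
        inner = disc_contour(20.0, n=2048)
        outer = disc_contour(23.0, n=2048)
        pts = sample_equidistant(inner, 64)
        rep = surface_error(pts, outer)
        assert rep.mean_error == pytest.approx(3.0, abs=1e-3)
        assert rep.n_points == 64

    def test_empty_inputs_rejected(self):
        with pytest.raises(MetricsError):
            surface_error(np.empty((0, 3)),
                          trimesh.creation.icosphere(1, radius=5.0))


class TestChartModel:
    def test_published_3cm_row_dimensions(self):
        """3 cm probe: proximal depth 9, distal 16 -> axial extent 25 mm,
        radial extent 30 mm."""
        cm = build_chart_model(30.0)
        assert cm.axial_extent == pytest.approx(25.0)
        assert cm.radial_extent == pytest.approx(30.0)
        lo, hi = cm.surface.bounds
        assert hi[2] - lo[2] == pytest.approx(25.0, abs=1e-9)
        assert hi[0] - lo[0] == pytest.approx(30.0, abs=1e-9)

    def test_volume_matches_half_ellipsoid_closed_form(self):
        cm = build_chart_model(30.0)
        exact = (2 * np.pi / 3) * 15 * 15 * 9 + (2 * np.pi / 3) * 15 * 15 * 16
        assert cm.closed_form_volume == pytest.approx(exact)
        assert abs(cm.surface.volume) == pytest.approx(exact, rel=0.01)
        assert cm.surface.is_watertight

    def test_rigid_pose_preserves_pairwise_distances(self):
        pose = RigidTransform.from_axis_angle([0, 1, 0], 1.1, [20, 5, -7])
        cm0 = build_chart_model(30.0)
        cm1 = build_chart_model(30.0, pose=pose)
        v0 = cm0.surface.vertices
        v1 = cm1.surface.vertices
        d0 = np.linalg.norm(v0[1:] - v0[0], axis=1)
        d1 = np.linalg.norm(v1[1:] - v1[0], axis=1)
        np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_unsupported_diameter_raises(self):
        with pytest.raises(MetricsError):
            build_chart_model(20.0)


class TestPairedComparison:
    def test_matches_textbook_closed_form(self):
        """t = mean(d) / (sd(d)/sqrt(n)) on a fixed 4-pair vector."""
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 5.0, 7.0])
        res = paired_comparison(a, b)
        d = a - b
        t_exact = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        assert res.statistic == pytest.approx(t_exact, rel=1e-12)
        assert res.dof == 3
        from scipy import stats
        p_exact = 2 * stats.t.sf(abs(t_exact), 3)
        assert res.p_value == pytest.approx(p_exact, rel=1e-12)

    def test_swapping_flips_sign_keeps_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 5.0, 7.0])
        r1 = paired_comparison(a, b)
        r2 = paired_comparison(b, a)
        assert r2.statistic == pytest.approx(-r1.statistic)
        assert r2.p_value == pytest.approx(r1.p_value)

    def test_zero_variance_differences_reported_not_valued(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateComparisonError):
            paired_comparison(a, a + 0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricsError):
            paired_comparison([1.0, 2.0], [1.0, 2.0, 3.0])
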