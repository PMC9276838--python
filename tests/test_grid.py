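"""Discretisation and diffusion-operator contracts."""

import numpy as np
import pytest

from rfasim import geometry as geo
from rfasim.fixtures import make_phantom_fixture
from rfasim.geometry import build_box_scene, build_concentric_sphere_scene
from rfasim.grid import (DiffusionOperator, DiscretizationError,
                         discretize_scene)


@pytest.fixture(scope="module")
def phantom_domain():
    scene, _ = make_phantom_fixture(None)
    return discretize_scene(scene, 3.0)


@pytest.fixture(scope="module")
def vessel_domain():
    scene, _ = make_phantom_fixture(25.0)
    return discretize_scene(scene, 3.0)


class TestDiscretizeScene:
    def test_boundary_label_sets_present(self, phantom_domain):
        labels = phantom_domain.boundary_labels
        for name in ("electrode_surface", "ground", "insulated_exterior"):
            assert len(labels[name]) > 0, name

    def test_electrode_and_ground_disjoint(self, phantom_domain):
        e = set(phantom_domain.boundary_labels["electrode_surface"])
        g = set(phantom_domain.boundary_labels["ground"])
        assert not (e & g)

    def test_vessel_wall_only_with_vessel(self, phantom_domain, vessel_domain):
        assert "vessel_wall" not in phantom_domain.boundary_labels
        assert len(vessel_domain.boundary_labels["vessel_wall"]) > 0

    def test_refinement_increases_cell_count(self):
        scene = build_box_scene((20.0, 20.0, 20.0))
        coarse = discretize_scene(scene, 2.0)
        fine = discretize_scene(scene, 1.0)
        # 3D refinement by 2 gives ~8x cells (boundary effects allowed)
        assert fine.n_free >= 4 * coarse.n_free

    def test_too_coarse_for_tines_raises(self):
        scene, _ = make_phantom_fixture(None)
        with pytest.raises(DiscretizationError):
            discretize_scene(scene, 25.0)

    def test_nonpositive_resolution_rejected(self):
        scene = build_box_scene((10.0, 10.0, 10.0))
        with pytest.raises(DiscretizationError):
            discretize_scene(scene, 0.0)


@pytest.fixture(scope="module")
def box_domain():
    return discretize_scene(build_box_scene((20.0, 10.0, 10.0),
                                            dirichlet_axis=0), 1.0)


class TestDiffusionOperator:
    def test_operator_symmetric(self, box_domain):
        A = DiffusionOperator(box_domain, np.ones(box_domain.n_free)).matrix
        assert abs(A - A.T).max() == 0.0

    def test_interior_row_sums_zero(self, phantom_domain):
        """Discrete conservation: rows without boundary faces sum to zero."""
        op = DiffusionOperator(phantom_domain,
                               np.ones(phantom_domain.n_free),
                               include_boundary=False)
        row_sums = np.asarray(op.matrix.sum(axis=1)).ravel()
        np.testing.assert_allclose(row_sums, 0.0, atol=1e-12)

    def test_linear_profile_exact_between_dirichlet_faces(self, box_domain):
        """Uniform coefficient, opposite faces at 0 and 1: linear solution
        is reproduced to solver precision (exact for this stencil)."""
        import scipy.sparse.linalg as spla
        op = DiffusionOperator(box_domain, np.ones(box_domain.n_free))
        bvals = np.zeros(box_domain.n_cells)
        bvals[box_domain.material == geo.ELECTRODE] = 1.0
        rhs = op.dirichlet_rhs(bvals)
        u = spla.spsolve(op.matrix.tocsc(), rhs)
        x = box_domain.free_centers()[:, 0]
        expected = 1.0 - x / 20.0
        np.testing.assert_allclose(u, expected, atol=1e-8)

    def test_two_material_series_flux_matches_harmonic_mean(self):
        """Slab of k1 then k2 in series: interface flux equals the
        1D closed form (t_hot - t_cold) / (L1/k1 + L2/k2)."""
        import scipy.sparse.linalg as spla
        scene = build_box_scene((20.0, 6.0, 6.0), dirichlet_axis=0)
        dom = discretize_scene(scene, 1.0)
        x = dom.free_centers()[:, 0]
        k1, k2 = 0.5, 2.0
        coeff = np.where(x <= 10.0, k1, k2)
        op = DiffusionOperator(dom, coeff)
        bvals = np.zeros(dom.n_cells)
        bvals[dom.material == geo.ELECTRODE] = 100.0
        u = spla.spsolve(op.matrix.tocsc(), op.dirichlet_rhs(bvals))
        flux = op.boundary_fluxes(u, bvals)
        hot = dom.material[dom.edges.fd_dir] == geo.ELECTRODE
        area = (dom.spacing * 1e-3) ** 2 * hot.sum()
        flux_per_area = -flux[hot].sum() / area
        exact = 100.0 / (0.010 / k1 + 0.010 / k2)
        assert flux_per_area == pytest.approx(exact, rel=1e-9)

    def test_nonpositive_coefficient_rejected(self, box_domain):
        bad = np.ones(box_domain.n_free)
        bad[0] = 0.0
        with pytest.raises(ValueError):
            DiffusionOperator(box_domain, bad)

    def test_maximum_principle(self):
        """No interior sources: the solution lies within the boundary
        values everywhere."""
        import scipy.sparse.linalg as spla
        scene = build_concentric_sphere_scene(2.0, 15.0)
        dom = discretize_scene(scene, 1.0)
        op = DiffusionOperator(dom, np.ones(dom.n_free))
        bvals = np.zeros(dom.n_cells)
        bvals[dom.material == geo.ELECTRODE] = 1.0
        u = spla.spsolve(op.matrix.tocsc(), op.dirichlet_rhs(bvals))
        assert u.min() >= -1e-12
        assert u.max() <= 1.0 + 1e-12


def test_export_vtk_writes_readable_header(tmp_path, box_domain):
    from rfasim.grid import export_vtk
    path = tmp_path / "dom.vtk"
    export_vtk(box_domain, path,
               fields={"ones": np.ones(box_domain.n_cells)})
    head = path.read_text().splitlines()
    assert head[0].startswith("# vtk DataFile")
    assert any(l.startswith("DIMENSIONS") for l in head[:8])
    assert "SCALARS material" in path.read_text()
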