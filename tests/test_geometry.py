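"""Electrode and scene construction geometry."""

import numpy as np
import pytest

from rfasim import geometry as geo
from rfasim.geometry import (GeometryError, PhantomSpec, VesselSpec,
                             build_leveen_electrode, build_phantom_scene)


class TestLeveenElectrode:
    @pytest.mark.parametrize("diameter,n_tines,fraction,expected_extent", [
        (30.0, 10, 1.0, 15.0),
        (40.0, 12, 1.0, 20.0),
        (30.0, 10, 0.5, 7.5),     # deployment scales the radial extent
        (20.0, 8, 1.0, 10.0),
    ])
    def test_radial_extent_matches_nominal_diameter(
            self, diameter, n_tines, fraction, expected_extent):
        e = build_leveen_electrode(diameter, n_tines, fraction)
        assert e.max_radial_extent() == pytest.approx(expected_extent)
        assert len(e.tine_paths) == n_tines

    def test_partial_deployment_scales_every_tine_consistently(self):
        full = build_leveen_electrode(30.0, 10, 1.0)
        half = build_leveen_electrode(30.0, 10, 0.5)
        for pf, ph in zip(full.tine_paths, half.tine_paths):
            np.testing.assert_allclose(ph - half.tip_position,
                                       0.5 * (pf - full.tip_position),
                                       atol=1e-12)

    def test_tines_start_at_tip(self, electrode_30):
        for path in electrode_30.tine_paths:
            np.testing.assert_allclose(path[0], electrode_30.tip_position,
                                       atol=1e-12)

    def test_tines_rotationally_symmetric(self, electrode_30):
        # all tines have identical radial/axial profiles about the shaft
        axis = electrode_30.shaft_axis
        profiles = []
        for path in electrode_30.tine_paths:
            rel = path - electrode_30.tip_position
            axial = rel @ axis
            radial = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
            profiles.append(np.column_stack([axial, radial]))
        for p in profiles[1:]:
            np.testing.assert_allclose(p, profiles[0], atol=1e-9)

    def test_tine_paths_are_simple(self, electrode_30):
        # consecutive points strictly advance in arc length (no doubling back)
        for path in electrode_30.tine_paths:
            seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
            assert np.all(seg > 0)

    @pytest.mark.parametrize("kwargs", [
        {"nominal_diameter": 15.0, "n_tines": 10, "deployed_fraction": 1.0},
        {"nominal_diameter": 45.0, "n_tines": 10, "deployed_fraction": 1.0},
        {"nominal_diameter": 30.0, "n_tines": 3, "deployed_fraction": 1.0},
        {"nominal_diameter": 30.0, "n_tines": 10, "deployed_fraction": 0.0},
        {"nominal_diameter": 30.0, "n_tines": 10, "deployed_fraction": 1.2},
    ])
    def test_out_of_range_parameters_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            build_leveen_electrode(**kwargs)


class TestPhantomScene:
    def test_two_litre_default(self):
        assert PhantomSpec().volume_litres == pytest.approx(2.0, rel=0.01)

    def test_vessel_offset_is_centerline_distance(self, electrode_40):
        scene = build_phantom_scene(PhantomSpec(), electrode_40,
                                    vessel_offset=35.0)
        v = scene.vessels[0]
        # centerline at 35 mm from the shaft axis (x=0 line)
        assert np.hypot(v.centerline[0, 0], v.centerline[0, 1]) == \
            pytest.approx(35.0)
        # lumen wall at offset - radius from the axis
        wall = 35.0 - v.diameter / 2.0
        assert wall == pytest.approx(32.5)

    def test_material_partition_is_exhaustive_and_unique(self, electrode_40, rng):
        scene = build_phantom_scene(PhantomSpec(), electrode_40,
                                    vessel_offset=25.0)
        pts = rng.uniform(-70, 170, size=(4000, 3))
        codes = scene.material_at(pts)
        assert codes.shape == (4000,)
        valid = {geo.OUTSIDE, geo.TISSUE, geo.VESSEL_LUMEN, geo.ELECTRODE,
                 geo.SHAFT, geo.GROUND}
        assert set(np.unique(codes)) <= valid

    def test_vessel_material_present_only_when_requested(self, electrode_40):
        with_v = build_phantom_scene(PhantomSpec(), electrode_40,
                                     vessel_offset=25.0)
        without = build_phantom_scene(PhantomSpec(), electrode_40)
        xs = np.linspace(-60, 60, 121)
        pts = np.column_stack([xs, np.zeros_like(xs),
                               np.full_like(xs, 83.0)])
        assert np.any(with_v.material_at(pts) == geo.VESSEL_LUMEN)
        assert not np.any(without.material_at(pts) == geo.VESSEL_LUMEN)

    def test_vessel_outside_beaker_rejected(self, electrode_40):
        with pytest.raises(GeometryError):
            build_phantom_scene(PhantomSpec(), electrode_40,
                                vessel_offset=61.0)

    def test_ground_below_beaker_bottom(self, electrode_40):
        scene = build_phantom_scene(PhantomSpec(), electrode_40)
        below = np.array([[10.0, 0.0, -1.0]])
        assert scene.material_at(below)[0] == geo.GROUND


class TestVesselSpec:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(GeometryError):
            VesselSpec(centerline=np.zeros((2, 3)), diameter=0.0)
        with pytest.raises(GeometryError):
            VesselSpec(centerline=np.zeros((2, 3)), flow_speed=-1.0)

    def test_bench_defaults(self):
        v = VesselSpec(centerline=np.zeros((2, 3)))
        assert v.diameter == 5.0
        assert v.flow_speed == pytest.approx(105.0)  # 10.5 cm/s
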