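"""Phantom generator: analytic ground truth and rasterization contracts."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orbitarea import (
    CohortRanges,
    PhantomSpec,
    defect_boundary_polygon,
    projected_defect_area,
    rasterize_phantom,
    sample_cohort,
    true_defect_area,
)


def cap_area_by_triangulation(R: float, a: float, n_theta: int = 400, n_phi: int = 400) -> float:
    """Independent oracle: dense parametric triangulation of the spherical cap."""
    theta_max = math.asin(a / R)
    theta = np.linspace(0.0, theta_max, n_theta)
    phi = np.linspace(0.0, 2 * math.pi, n_phi)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    X = R * np.sin(T) * np.cos(P)
    Y = R * np.sin(T) * np.sin(P)
    Z = R * np.cos(T)
    area = 0.0
    for i in range(n_theta - 1):
        for j in range(n_phi - 1):
            q = np.array(
                [
                    [X[i, j], Y[i, j], Z[i, j]],
                    [X[i + 1, j], Y[i + 1, j], Z[i + 1, j]],
                    [X[i + 1, j + 1], Y[i + 1, j + 1], Z[i + 1, j + 1]],
                    [X[i, j + 1], Y[i, j + 1], Z[i, j + 1]],
                ]
            )
            area += 0.5 * np.linalg.norm(np.cross(q[1] - q[0], q[2] - q[0]))
            area += 0.5 * np.linalg.norm(np.cross(q[2] - q[0], q[3] - q[0]))
    return area


class TestTrueDefectArea:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(), math.pi * 100.0),  # flat circle r=10
            (dict(floor_kind="tilted_plane", tilt_deg=60.0), math.pi * 100.0),  # isometry
            (
                dict(defect_shape="ellipse", semi_axis_a_mm=12.0, semi_axis_b_mm=8.0),
                math.pi * 96.0,
            ),
        ],
    )
    def test_planar_defects(self, kwargs, expected):
        assert true_defect_area(PhantomSpec(**kwargs)) == pytest.approx(expected, rel=1e-12)

    def test_cap_formula_matches_triangulation_oracle(self):
        spec = PhantomSpec(floor_kind="spherical_cap", cap_radius_mm=20.0)
        closed_form = true_defect_area(spec)
        assert closed_form == pytest.approx(2 * math.pi * 20 * (20 - math.sqrt(300)), rel=1e-12)
        assert closed_form == pytest.approx(336.7149, abs=5e-4)
        assert closed_form == pytest.approx(cap_area_by_triangulation(20.0, 10.0), rel=1e-3)

    @given(tilt=st.floats(0.0, 80.0))
    @settings(deadline=None, max_examples=30)
    def test_tilt_never_changes_intrinsic_area_but_shrinks_projection(self, tilt):
        spec = PhantomSpec(
            floor_kind="tilted_plane",
            tilt_deg=tilt,
            semi_axis_a_mm=6.0,
            semi_axis_b_mm=6.0,
            volume_extent_mm=(40.0, 40.0, 60.0),
        )
        assert true_defect_area(spec) == pytest.approx(math.pi * 36.0, rel=1e-12)
        assert projected_defect_area(spec) == pytest.approx(
            math.pi * 36.0 * math.cos(math.radians(tilt)), rel=1e-12
        )

    def test_defect_larger_than_floor_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(semi_axis_a_mm=25.0, semi_axis_b_mm=25.0)
        with pytest.raises(ValueError):
            PhantomSpec(floor_kind="spherical_cap", cap_radius_mm=12.0)  # a=10 near R


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(floor_kind="dome"),
            dict(tilt_deg=85.0),
            dict(tilt_deg=-1.0),
            dict(shell_thickness_mm=0.0),
            dict(bone_hu=40.0, tissue_hu=40.0),
            dict(noise_sd_hu=-1.0),
            dict(voxel_spacing_mm=(0.4, 0.0, 0.4)),
            dict(defect_shape="circle", semi_axis_a_mm=10.0, semi_axis_b_mm=8.0),
            dict(floor_kind="spherical_cap", defect_shape="ellipse",
                 semi_axis_a_mm=10.0, semi_axis_b_mm=8.0),
        ],
    )
    def test_invalid_specs_raise(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)


class TestBoundaryPolygon:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(),
            dict(floor_kind="tilted_plane", tilt_deg=37.0),
            dict(floor_kind="spherical_cap", cap_radius_mm=18.0),
        ],
    )
    def test_rim_lies_on_analytic_surface(self, kwargs):
        spec = PhantomSpec(**kwargs)
        poly = defect_boundary_polygon(spec)
        c = spec.floor_center()
        if spec.floor_kind == "spherical_cap":
            cs = spec.sphere_center()
            r = np.linalg.norm(poly - cs, axis=1)
            assert np.abs(r - spec.cap_radius_mm).max() < 1e-9
        else:
            th = spec.tilt_rad
            n = np.array([0.0, -math.sin(th), math.cos(th)])
            assert np.abs((poly - c) @ n).max() < 1e-9

    def test_rim_is_closed_simple_loop(self):
        from shapely.geometry import Polygon

        poly = defect_boundary_polygon(PhantomSpec(floor_kind="tilted_plane", tilt_deg=30.0))
        assert Polygon(poly[:, :2]).is_valid


class TestRasterize:
    def test_noiseless_volume_has_exactly_three_levels(self, flat_phantom):
        spec, volume, _truth = flat_phantom
        levels = np.unique(volume.values)
        assert set(levels) == {spec.air_hu, spec.tissue_hu, spec.bone_hu}

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(noise_sd_hu=25.0, seed=123)
        v1, _ = rasterize_phantom(spec)
        v2, _ = rasterize_phantom(spec)
        assert np.array_equal(v1.values, v2.values)
        v3, _ = rasterize_phantom(replace(spec, seed=124))
        assert not np.array_equal(v1.values, v3.values)

    def test_bone_voxel_count_matches_analytic_shell_volume(self, flat_phantom):
        spec, volume, _truth = flat_phantom
        bone = volume.values == spec.bone_hu
        measured = bone.sum() * volume.voxel_volume_mm3()
        ex, ey, _ez = spec.volume_extent_mm
        floor_area = ex * ey - math.pi * spec.semi_axis_a_mm * spec.semi_axis_b_mm
        expected = floor_area * spec.shell_thickness_mm
        # one voxel-layer tolerance on the shell volume
        layer = floor_area * max(spec.voxel_spacing_mm)
        assert abs(measured - expected) < layer

    def test_resolution_convergence_of_shell_volume(self):
        spec = PhantomSpec(floor_kind="tilted_plane", tilt_deg=25.0)
        errors = []
        for f in (1.0, 0.5):
            s = replace(spec, voxel_spacing_mm=tuple(f * v for v in spec.voxel_spacing_mm))
            volume, _ = rasterize_phantom(s)
            bone = (volume.values == spec.bone_hu).sum() * volume.voxel_volume_mm3()
            ex, ey, ez = spec.volume_extent_mm
            # analytic volume of the clipped tilted slab minus the defect channel
            th = spec.tilt_rad
            plane_area = _clipped_plane_area(spec)
            expected = (plane_area - math.pi * 100.0) * spec.shell_thickness_mm
            errors.append(abs(bone - expected) / expected)
        assert errors[1] < errors[0]

    def test_truth_consistency(self, cap_phantom):
        spec, _volume, truth = cap_phantom
        assert truth.true_area_3d >= truth.projected_area
        assert truth.true_area_3d == pytest.approx(true_defect_area(spec), rel=1e-12)


def _clipped_plane_area(spec):
    """In-plane area of the tilted floor inside the volume box (numerical)."""
    ex, ey, ez = spec.volume_extent_mm
    c = spec.floor_center()
    th = spec.tilt_rad
    u = np.linspace(0.0, ex, 400)
    v = np.linspace(-60.0, 60.0, 4000)
    U, V = np.meshgrid(u, v, indexing="ij")
    y = c[1] + V * math.cos(th)
    z = c[2] + V * math.sin(th)
    inside = (y >= 0) & (y <= ey - 1e-9) & (z >= 0) & (z <= ez - 1e-9)
    du = u[1] - u[0]
    dv = v[1] - v[0]
    return inside.sum() * du * dv


class TestSampleCohort:
    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            sample_cohort(0, seed=1)

    def test_reproducible_and_sized(self):
        a = sample_cohort(20, seed=7)
        b = sample_cohort(20, seed=7)
        assert len(a) == 20
        assert a == b
        assert sample_cohort(20, seed=8) != a

    def test_areas_span_configured_range(self):
        ranges = CohortRanges(area_range_mm2=(80.0, 400.0))
        specs = sample_cohort(60, ranges, seed=3)
        areas = np.array([true_defect_area(s) for s in specs])
        assert areas.min() >= 80.0 - 1e-9
        assert areas.max() <= 400.0 + 1e-9
        kinds = {s.floor_kind for s in specs}
        assert kinds == {"flat", "tilted_plane", "spherical_cap"}

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            CohortRanges(area_range_mm2=(400.0, 100.0))
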