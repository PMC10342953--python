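"""Root-motion metrics: decomposition, angles, distensibility, pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from rootmotion import (
    AnalysisPlane,
    Centerline,
    DeformationParams,
    MetricsError,
    TriSurfaceMesh,
    VertexDisplacementField,
    aortic_rotation,
    apply_deformation,
    axial_tilt,
    compute_root_metrics,
    decompose_displacement,
    distensibility,
    lv_ao_angle,
    mean_plane_displacement,
)
from rootmotion.geometry import contour_centroid, slice_mesh

from conftest import random_rigid_transform
from test_geometry import tube_mesh


class TestDecomposition:
    @pytest.mark.parametrize(
        "vec,n,expected",
        [
            ((0, 0, 5), (0, 0, 1), (5, 5, 0, 1, 0)),
            ((3, 4, 0), (0, 0, 1), (5, 0, 5, 0, 1)),
            ((3, 0, 4), (0, 0, 1), (5, 4, 3, 0.8, 0.6)),
        ],
    )
    def test_pythagorean_examples(self, vec, n, expected):
        d = decompose_displacement(vec, n)
        assert (d.total, d.axial, d.inplane, d.rel_axial, d.rel_inplane) == \
            pytest.approx(expected, abs=1e-12)
        assert d.rel_axial**2 + d.rel_inplane**2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_displacement_flags_relatives_undefined(self):
        d = decompose_displacement((0, 0, 0), (0, 0, 1))
        assert d.total == 0
        assert math.isnan(d.rel_axial) and math.isnan(d.rel_inplane)

    def test_non_unit_normal_rejected(self):
        with pytest.raises(MetricsError):
            decompose_displacement((1, 0, 0), (0, 0, 2))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(-20, 20), min_size=3, max_size=3),
           st.integers(0, 10_000))
    def test_relative_components_on_unit_circle(self, vec, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3)
        n /= np.linalg.norm(n)
        d = decompose_displacement(vec, n)
        if d.total > 1e-12:
            assert d.rel_axial**2 + d.rel_inplane**2 == pytest.approx(1.0, abs=1e-9)
        assert d.total == pytest.approx(math.hypot(d.axial, d.inplane), abs=1e-9)


class TestAxialTilt:
    def test_identical_normals_zero(self):
        assert axial_tilt((0, 0, 1), (0, 0, 1)) == 0.0

    def test_constructed_rotation_recovered(self):
        n = np.array([0, 0, 1.0])
        n_sys = Rotation.from_euler("x", 5, degrees=True).apply(n)
        assert axial_tilt(n, n_sys) == pytest.approx(5.0, abs=1e-9)

    def test_orientation_flip_gives_acute_angle(self):
        n = np.array([0, 0, 1.0])
        n_sys = Rotation.from_euler("x", 177, degrees=True).apply(n)
        assert axial_tilt(n, n_sys) == pytest.approx(3.0, abs=1e-9)

    def test_random_normals_match_cross_dot_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b = rng.normal(size=3), rng.normal(size=3)
            a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
            bo = b if a @ b >= 0 else -b
            oracle = math.degrees(math.atan2(np.linalg.norm(np.cross(a, bo)), a @ bo))
            assert axial_tilt(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_non_unit_inputs_rejected(self):
        with pytest.raises(MetricsError):
            axial_tilt((0, 0, 2), (0, 0, 1))


class TestAorticRotation:
    def setup_method(self):
        self.plane = AnalysisPlane.from_normal([0, 0, 0.0], [0, 0, 1.0])

    def test_pure_twist_recovered(self):
        c = np.zeros(3)
        ref = np.array([15.0, 0, 0])
        ref_sys = Rotation.from_euler("z", 10, degrees=True).apply(ref)
        assert aortic_rotation(c, c, ref, ref_sys, self.plane) == pytest.approx(10.0, abs=1e-9)

    def test_translation_invariance(self):
        c = np.zeros(3)
        ref = np.array([15.0, 3, 0])
        t = np.array([4.0, -2.0, 1.0])
        assert aortic_rotation(c, c + t, ref, ref + t, self.plane) == pytest.approx(0.0, abs=1e-9)

    def test_matches_planar_atan2_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            cd, cs = rng.normal(size=3), rng.normal(size=3)
            rd, rs = cd + rng.normal(size=3) * 10, cs + rng.normal(size=3) * 10
            v1, v2 = rd - cd, rs - cs
            p1 = np.array([v1 @ self.plane.u, v1 @ self.plane.v])
            p2 = np.array([v2 @ self.plane.u, v2 @ self.plane.v])
            oracle = abs(math.degrees(
                math.atan2(p1[0] * p2[1] - p1[1] * p2[0], p1 @ p2)))
            got = aortic_rotation(cd, cs, rd, rs, self.plane)
            assert got == pytest.approx(oracle, abs=1e-9)

    def test_signed_variant_consistent(self):
        c = np.zeros(3)
        ref = np.array([15.0, 0, 0])
        ref_sys = Rotation.from_euler("z", -7, degrees=True).apply(ref)
        s = aortic_rotation(c, c, ref, ref_sys, self.plane, signed=True)
        assert s == pytest.approx(-7.0, abs=1e-9)
        assert aortic_rotation(c, c, ref, ref_sys, self.plane) == pytest.approx(7.0, abs=1e-9)

    def test_reference_along_normal_rejected(self):
        with pytest.raises(MetricsError):
            aortic_rotation([0, 0, 0], [0, 0, 0], [0, 0, 5.0], [1, 0, 0], self.plane)


class TestDistensibility:
    @pytest.mark.parametrize(
        "adia,asys,pp,ratio,dist",
        [
            (100.0, 110.0, 50.0, 1.1, 2.0),
            (200.0, 200.0, 56.0, 1.0, 0.0),
            (314.16, 351.86, 56.0, 351.86 / 314.16, (351.86 / 314.16 - 1) / 56 * 1e3),
        ],
    )
    def test_hand_evaluations(self, adia, asys, pp, ratio, dist):
        r, d = distensibility(adia, asys, pp)
        assert r == pytest.approx(ratio, rel=1e-12)
        assert d == pytest.approx(dist, rel=1e-12)
        # the third case lands near the canonical 1.12 / 2.14e-3 values
        if adia == 314.16:
            assert r == pytest.approx(1.12, abs=1e-3)
            assert d == pytest.approx(2.142857, abs=1e-2)

    def test_linear_in_systolic_area_and_pp_scaling(self):
        _, d1 = distensibility(100, 108, 50)
        _, d2 = distensibility(100, 116, 50)
        _, half = distensibility(100, 108, 100)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)
        assert half == pytest.approx(d1 / 2, rel=1e-12)

    @pytest.mark.parametrize("adia,pp", [(0.0, 50.0), (-5.0, 50.0), (100.0, 0.0)])
    def test_invalid_inputs_rejected(self, adia, pp):
        with pytest.raises(MetricsError):
            distensibility(adia, 110.0, pp)


def _ring(center, normal, radius, n=12, jitter=0.0, rng=None):
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    a = np.cross(normal, [1.0, 0, 0])
    if np.linalg.norm(a) < 1e-6:
        a = np.cross(normal, [0, 1.0, 0])
    a /= np.linalg.norm(a)
    b = np.cross(normal, a)
    th = 2 * np.pi * np.arange(n) / n
    pts = center + radius * (np.outer(np.cos(th), a) + np.outer(np.sin(th), b))
    if jitter:
        pts = pts + rng.normal(scale=jitter, size=pts.shape)
    return pts


class TestLvAoAngle:
    def test_coaxial_limit_is_180(self):
        ao = _ring([0, 0, 10.0], [0, 0, 1], 12.0)
        mi = _ring([0, 0, 0.0], [0, 0, 1], 15.0)
        phi = lv_ao_angle(ao, mi, lv_apex_hint=[0, 0, -40], aorta_hint=[0, 0, 40])
        assert phi.phi_deg == pytest.approx(180.0, abs=1e-9)

    def test_fifty_degree_normals_give_130(self):
        n_mi = [math.sin(math.radians(50)), 0, math.cos(math.radians(50))]
        ao = _ring([0, 0, 10.0], [0, 0, 1], 12.0)
        mi = _ring([-25, 0, 0.0], n_mi, 15.0)
        phi = lv_ao_angle(ao, mi, lv_apex_hint=np.array([-25, 0, 0]) - 40 * np.array(n_mi),
                          aorta_hint=[0, 0, 40])
        assert phi.phi_deg == pytest.approx(130.0, abs=1e-9)

    def test_jittered_47_degree_construction(self):
        rng = np.random.default_rng(21)
        n_mi = [math.sin(math.radians(47)), 0, math.cos(math.radians(47))]
        ao = _ring([0, 0, 10.0], [0, 0, 1], 12.0, n=24, jitter=0.01, rng=rng)
        mi = _ring([-25, 0, 0.0], n_mi, 15.0, n=24, jitter=0.01, rng=rng)
        phi = lv_ao_angle(ao, mi, lv_apex_hint=np.array([-25, 0, 0]) - 40 * np.array(n_mi),
                          aorta_hint=[0, 0, 40])
        assert phi.phi_deg == pytest.approx(133.0, abs=0.1)

    def test_collinear_annulus_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        ao = _ring([0, 0, 10.0], [0, 0, 1], 12.0)
        with pytest.raises(Exception):
            lv_ao_angle(ao, line, [0, 0, -40], [0, 0, 40])


class TestMeanPlaneDisplacement:
    def setup_method(self):
        self.mesh = tube_mesh(radius=10.0, z0=-5, z1=5, n_circ=96, n_z=12)
        self.plane = AnalysisPlane.from_normal([0, 0, 0.0], [0, 0, 1.0])

    def test_uniform_field_is_identity(self):
        field = VertexDisplacementField(np.tile([0.0, 0, 5], (self.mesh.n_vertices, 1)))
        mean = mean_plane_displacement(self.mesh, field, self.plane)
        assert mean == pytest.approx([0, 0, 5], abs=1e-12)

    def test_radial_dilation_cancels_by_symmetry(self):
        v = self.mesh.vertices
        radial = np.column_stack([v[:, 0], v[:, 1], np.zeros(len(v))]) * 0.1
        mean = mean_plane_displacement(self.mesh, VertexDisplacementField(radial), self.plane)
        assert np.linalg.norm(mean) < 1e-6 * 10.0

    def test_linear_field_mean_is_value_at_centroid(self):
        A = np.array([[0.02, 0.01, 0.0], [-0.03, 0.05, 0.01], [0.0, 0.02, -0.04]])
        shifted = tube_mesh(radius=10.0, z0=-5, z1=5, n_circ=96, n_z=12, center=(3.0, -2.0))
        field = VertexDisplacementField(shifted.vertices @ A.T)
        mean = mean_plane_displacement(shifted, field, self.plane)
        contour = slice_mesh(shifted, self.plane)
        centroid = contour_centroid(contour)
        assert mean == pytest.approx(A @ centroid, abs=1e-4)

    def test_field_mesh_size_mismatch_rejected(self):
        with pytest.raises(MetricsError):
            mean_plane_displacement(
                self.mesh, VertexDisplacementField(np.zeros((5, 3))), self.plane
            )


class TestPipeline:
    def test_identity_field_null_metrics(self, default_phantom):
        _, mesh, cl, lm, _ = default_phantom
        field = VertexDisplacementField(np.zeros((mesh.n_vertices, 3)))
        m = compute_root_metrics(mesh, field, cl, lm, 56.0)
        assert m.total_disp == 0 and m.axial_disp == 0 and m.inplane_disp == 0
        assert math.isnan(m.rel_axial) and math.isnan(m.rel_inplane)
        assert m.axial_tilt_deg == pytest.approx(0.0, abs=1e-9)
        assert m.rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert m.area_ratio == pytest.approx(1.0, rel=1e-12)
        assert m.distensibility == pytest.approx(0.0, abs=1e-12)

    def test_pure_axial_translation(self, run_phantom_pipeline):
        m, _ = run_phantom_pipeline(DeformationParams(axial_translation=5.0))
        assert m.total_disp == pytest.approx(5.0, rel=1e-6)
        assert m.rel_axial == pytest.approx(1.0, abs=1e-6)
        assert m.inplane_disp == pytest.approx(0.0, abs=1e-5)
        assert m.axial_tilt_deg == pytest.approx(0.0, abs=1e-6)

    def test_pure_translation_leaves_tilt_and_rotation_zero(self, run_phantom_pipeline):
        m, _ = run_phantom_pipeline(
            DeformationParams(axial_translation=3.0, inplane_translation=(2.0, -1.0))
        )
        assert m.axial_tilt_deg <= 1e-9
        assert m.rotation_deg <= 1e-9

    def test_full_phantom_recovery(self, run_phantom_pipeline):
        m, truth = run_phantom_pipeline(DeformationParams(
            axial_translation=5.0, inplane_translation=(3.0, 0.0),
            twist_deg=2.0, tilt_deg=3.0, dilation_factor=1.06,
        ))
        assert m.total_disp == pytest.approx(truth.total_disp, rel=0.02)
        assert m.rel_axial == pytest.approx(truth.rel_axial, abs=0.02)
        assert m.rel_inplane == pytest.approx(truth.rel_inplane, abs=0.02)
        assert m.axial_tilt_deg == pytest.approx(truth.tilt_deg, abs=0.3)
        assert m.rotation_deg == pytest.approx(truth.rotation_deg, abs=0.3)
        assert m.area_ratio == pytest.approx(truth.area_ratio, rel=0.01)
        assert m.distensibility == pytest.approx(truth.distensibility, rel=0.01)

    def test_rigid_invariance_of_all_metrics(self, default_phantom):
        _, mesh, cl, lm, plane = default_phantom
        dp = DeformationParams(axial_translation=4.0, inplane_translation=(2.0, 1.0),
                               twist_deg=3.0, tilt_deg=2.0, dilation_factor=1.08)
        field, _ = apply_deformation(mesh, cl, lm, dp, plane)
        base = compute_root_metrics(mesh, field, cl, lm, 56.0)
        rng = np.random.default_rng(17)
        for _ in range(3):
            rot, t = random_rigid_transform(rng)
            mesh2 = TriSurfaceMesh(mesh.vertices @ rot.T + t, mesh.triangles)
            field2 = VertexDisplacementField(field.vectors @ rot.T)
            cl2 = Centerline(cl.points @ rot.T + t)
            lm2 = dict(lm)
            for key in ("left_coronary_ostium", "right_coronary_ostium"):
                lm2[key] = (rot @ np.asarray(lm[key]) + t).tolist()
            m = compute_root_metrics(mesh2, field2, cl2, lm2, 56.0)
            for attr in ("total_disp", "axial_disp", "inplane_disp", "rel_axial",
                         "rel_inplane", "area_dia", "area_sys", "area_ratio"):
                assert getattr(m, attr) == pytest.approx(getattr(base, attr), abs=1e-6)
            for attr in ("axial_tilt_deg", "rotation_deg"):
                assert getattr(m, attr) == pytest.approx(getattr(base, attr), abs=1e-6)

    def test_missing_landmark_errors_with_stage_context(self, default_phantom):
        _, mesh, cl, lm, _ = default_phantom
        field = VertexDisplacementField(np.zeros((mesh.n_vertices, 3)))
        bad = {k: v for k, v in lm.items() if k != "left_coronary_ostium"}
        with pytest.raises(MetricsError, match="left_coronary_ostium"):
            compute_root_metrics(mesh, field, cl, bad, 56.0)
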