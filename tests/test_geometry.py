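import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wingkin.geometry import (Frame, RigidTransform, bone_local_frame,
                              build_global_frame, euler_zyx_to_matrix,
                              matrix_to_euler_zyx, rotation_about_line,
                              wrap_angle_deg)

angles = st.floats(-179.0, 179.0)
coords = st.floats(-100.0, 100.0)


class TestEulerConvention:
    def test_yaw_90_rotates_x_to_y(self):
        t = RigidTransform([90.0, 0.0, 0.0], [0.0, 0.0, 0.0])
        assert np.allclose(t.apply([1.0, 0.0, 0.0]), [0.0, 1.0, 0.0], atol=1e-12)

    def test_composition_order_is_z_then_y_then_x(self):
        a, b, g = 31.0, -22.0, 57.0
        rz = euler_zyx_to_matrix([a, 0, 0])
        ry = euler_zyx_to_matrix([0, b, 0])
        rx = euler_zyx_to_matrix([0, 0, g])
        assert np.allclose(euler_zyx_to_matrix([a, b, g]), rz @ ry @ rx, atol=1e-12)

    @given(a=angles, b=st.floats(-88.9, 88.9), g=angles)
    def test_round_trip_away_from_gimbal_lock(self, a, b, g):
        mat = euler_zyx_to_matrix([a, b, g])
        back = euler_zyx_to_matrix(matrix_to_euler_zyx(mat))
        assert np.allclose(mat, back, atol=1e-9)

    def test_gimbal_lock_reports_zero_roll(self):
        mat = euler_zyx_to_matrix([25.0, 90.0, 40.0])
        yaw, pitch, roll = matrix_to_euler_zyx(mat)
        assert roll == pytest.approx(0.0, abs=1e-9)
        assert pitch == pytest.approx(90.0, abs=1e-9)
        assert np.allclose(euler_zyx_to_matrix([yaw, pitch, roll]), mat, atol=1e-9)

    def test_wrap_angle_half_open_interval(self):
        assert wrap_angle_deg(180.0) == 180.0
        assert wrap_angle_deg(-180.0) == 180.0
        assert wrap_angle_deg(540.0) == 180.0
        assert wrap_angle_deg(190.0) == pytest.approx(-170.0)


class TestRigidTransform:
    def test_identity_leaves_points(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert np.allclose(RigidTransform.identity().apply(pts), pts)

    @given(a=angles, b=st.floats(-80, 80), g=angles, x=coords, y=coords, z=coords)
    def test_inverse_round_trip(self, a, b, g, x, y, z):
        t = RigidTransform([a, b, g], [x, y, z])
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 0.5, 9.0], [0.0, 0.0, 0.0]])
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_rotation_matrix_is_orthonormal(self):
        t = RigidTransform([33.0, -71.0, 12.0], [1.0, 2.0, 3.0])
        m = t.matrix
        assert np.linalg.norm(m @ m.T - np.eye(3)) < 1e-12
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)

    def test_compose_matches_sequential_application(self):
        t1 = RigidTransform([10, 20, 30], [1, 2, 3])
        t2 = RigidTransform([-40, 5, 60], [-2, 0, 7])
        pts = np.random.default_rng(1).normal(size=(5, 3))
        assert np.allclose((t1 @ t2).apply(pts), t1.apply(t2.apply(pts)), atol=1e-10)

    def test_rotation_about_line_fixes_the_line(self):
        point, axis = np.array([3.0, -2.0, 5.0]), np.array([1.0, 1.0, 0.2])
        t = rotation_about_line(point, axis, 73.0)
        for lam in (-2.0, 0.0, 1.5):
            p = point + lam * axis
            assert np.allclose(t.apply(p), p, atol=1e-10)

    def test_rejects_non_rotation_matrix(self):
        with pytest.raises(ValueError, match="rotation"):
            RigidTransform.from_matrix(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestGlobalFrame:
    def test_unit_landmarks_give_identity_frame(self):
        f = build_global_frame([0, 0, 0], [1, 0, 0], [0, 0, 1])
        assert np.allclose(f.axes, np.eye(3), atol=1e-12)

    def test_y_aligned_landmarks(self):
        f = build_global_frame([0, 0, 0], [0, 1, 0], [0, 0, 1])
        assert np.allclose(f.x, [0, 1, 0])
        assert np.allclose(f.z, [0, 0, 1])
        assert np.allclose(f.y, [-1, 0, 0])

    @given(hx=coords, hy=coords, hz=coords, mx=coords, my=coords, mz=coords)
    def test_axes_orthonormal_and_x_toward_metacarpal(self, hx, hy, hz, mx, my, mz):
        head, meta = np.array([hx, hy, hz]), np.array([mx, my, mz])
        d = meta - head
        if np.linalg.norm(d) < 1e-3 or np.linalg.norm(np.cross(d, [0, 0, 1.0])) < 1e-3:
            return
        f = build_global_frame(head, meta)
        assert np.linalg.norm(f.axes @ f.axes.T - np.eye(3)) < 1e-9
        assert np.linalg.det(f.axes) > 0
        assert f.x @ d > 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            build_global_frame([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="parallel"):
            build_global_frame([0, 0, 0], [0, 0, 5], [0, 0, 1])


class TestBoneLocalFrame:
    def setup_method(self):
        self.global_frame = build_global_frame([0, 0, 0], [1, 0, 0])

    def test_straight_centerline_along_x_is_axis_aligned(self):
        cl = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0.0]])
        f = bone_local_frame(cl, self.global_frame)
        assert np.allclose(f.axes, np.eye(3), atol=1e-12)
        assert np.allclose(f.origin, [10, 0, 0])

    def test_centerline_along_y(self):
        cl = np.array([[0, 0, 0], [0, 8, 0.0]])
        f = bone_local_frame(cl, self.global_frame)
        assert np.allclose(f.x, [0, 1, 0], atol=1e-12)

    def test_arc_midpoint_matches_numeric_arclength_oracle(self):
        # quarter-circle arc of radius 10: half arclength lies at 45 degrees
        theta = np.linspace(0, np.pi / 2, 2001)
        cl = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta), np.zeros_like(theta)])
        f = bone_local_frame(cl, self.global_frame)
        expected = 10 * np.array([np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0])
        assert np.allclose(f.origin, expected, atol=1e-4)

    def test_vertical_tangent_rejected(self):
        cl = np.array([[0, 0, 0], [0, 0, 9.0]])
        with pytest.raises(ValueError, match="perpendicular"):
            bone_local_frame(cl, self.global_frame)

    def test_frame_validation(self):
        with pytest.raises(ValueError, match="orthonormal"):
            Frame(np.zeros(3), np.eye(3) * 2.0)
        with pytest.raises(ValueError, match="left-handed"):
            Frame(np.zeros(3), np.array([[1, 0, 0], [0, 0, 1], [0, 1, 0.0]]))
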