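import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from wingkin.mechanism import WingGeometry, MechanismConfig
from wingkin.sensors import (joint_angle_series, q_angle_deg, q_canonical,
                             q_from_rotation, q_inverse, q_multiply,
                             q_normalize, quat_to_euler_zyx,
                             relative_quaternion, synthesize_streams)

IDENT = np.array([1.0, 0.0, 0.0, 0.0])


def qrot(axis, angle_deg):
    return q_from_rotation(Rotation.from_rotvec(
        np.radians(angle_deg) * np.asarray(axis, float) / np.linalg.norm(axis)))


unit_quats = st.tuples(*[st.floats(-1, 1) for _ in range(4)]).filter(
    lambda q: np.linalg.norm(q) > 1e-2).map(lambda q: q_normalize(np.array(q)))


class TestQuaternionAlgebra:
    def test_hamilton_product_i_j_is_k(self):
        i, j, k = [np.array([0.0, *v]) for v in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
        assert np.allclose(q_multiply(i, j), k)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            q_inverse(np.zeros(4))

    @given(q=unit_quats)
    def test_inverse_is_group_inverse(self, q):
        assert np.allclose(q_canonical(q_multiply(q, q_inverse(q))), IDENT, atol=1e-9)

    @given(q=unit_quats)
    def test_euler_round_trip_up_to_sign(self, q):
        e = quat_to_euler_zyx(q)
        back = q_from_rotation(Rotation.from_euler("ZYX", e, degrees=True))
        # double cover: q and -q are the same rotation (and the canonical
        # sign is ambiguous when the scalar part is ~0)
        assert min(np.abs(back - q).max(), np.abs(back + q).max()) < 1e-9


class TestRelativeQuaternion:
    def test_identity_at_reference_time(self):
        pa, pb = qrot([0, 0, 1], 40.0), qrot([1, 1, 0], -25.0)
        assert np.allclose(relative_quaternion(pa, pb, pa, pb), IDENT, atol=1e-12)

    def test_pure_extra_z_rotation_recovered(self):
        pa0 = qrot([0, 1, 0], 10.0)
        pb0 = qrot([1, 0, 0], -35.0)
        pb_t = q_multiply(qrot([0, 0, 1], 30.0), pb0)
        rel = relative_quaternion(pa0, pb_t, pa0, pb0)
        assert q_angle_deg(rel) == pytest.approx(30.0, abs=1e-9)

    @given(q=unit_quats)
    def test_invariant_under_common_body_rotation(self, q):
        pa0, pb0 = qrot([0, 0, 1], 15.0), qrot([0, 1, 0], 40.0)
        pa_t, pb_t = qrot([1, 0, 1], 22.0), qrot([1, 2, 0], -17.0)
        base = relative_quaternion(pa_t, pb_t, pa0, pb0)
        moved = relative_quaternion(q_multiply(q, pa_t), q_multiply(q, pb_t), pa0, pb0)
        assert np.allclose(base, moved, atol=1e-9)


class TestEulerExtraction:
    def test_identity_and_pure_yaw(self):
        assert np.allclose(quat_to_euler_zyx(IDENT), [0, 0, 0])
        assert np.allclose(quat_to_euler_zyx(qrot([0, 0, 1], 90.0)), [90, 0, 0],
                           atol=1e-9)

    def test_near_z_axis_rotation_concentrates_in_yaw(self):
        # pitch/roll of a rotation about an axis tilted by eps from Z stay
        # below arcsin-bounded leakage while yaw sweeps the stroke
        axis = np.array([0.02, 0.03, 1.0])
        tilt = np.degrees(np.arccos(axis[2] / np.linalg.norm(axis)))
        for ang in np.linspace(0, 50, 11):
            yaw, pitch, roll = quat_to_euler_zyx(qrot(axis, ang))
            assert abs(pitch) <= 2.0 and abs(roll) <= 2.0
            assert abs(pitch) <= np.degrees(np.arcsin(np.radians(tilt))) + ang * 0.05 + 1e-6
        assert quat_to_euler_zyx(qrot(axis, 50.0))[0] > 45.0


class TestJointAngleSeries:
    def test_static_sensors_give_identically_zero_series(self, mech_config):
        streams = synthesize_streams(mech_config, np.zeros(8), 0.0, np.arange(8.0))
        for series in joint_angle_series(streams):
            assert np.allclose(series.angle_deg, 0.0)
            assert np.allclose(series.euler_deg.to_numpy(), 0.0)

    def test_stroke_recovers_commanded_elbow_angle(self, mech_config):
        theta1 = np.linspace(0.0, 37.18, 40)
        streams = synthesize_streams(mech_config, theta1, 0.0,
                                     np.linspace(0, 5, 40))
        by_joint = {s.joint_id: s for s in joint_angle_series(streams)}
        assert by_joint[1].angle_deg[-1] == pytest.approx(37.18, abs=0.1)
        assert by_joint[2].angle_deg[-1] == pytest.approx(55.65, abs=0.1)
        assert np.allclose(by_joint[5].angle_deg, 0.0, atol=1e-9)

    def test_mounting_offsets_preserve_relative_angle(self, mech_config):
        mounts = {"S2": qrot([1, 0, 0], 25.0), "S3": qrot([0, 1, 0], -40.0)}
        theta1 = np.linspace(0.0, 37.18, 10)
        plain = synthesize_streams(mech_config, theta1, 0.0, np.arange(10.0))
        mounted = synthesize_streams(mech_config, theta1, 0.0, np.arange(10.0),
                                     mounts=mounts)
        a = {s.joint_id: s for s in joint_angle_series(plain)}
        b = {s.joint_id: s for s in joint_angle_series(mounted)}
        assert np.allclose(a[1].angle_deg, b[1].angle_deg, atol=1e-9)

    def test_chain_composition_of_raw_relatives(self, mech_config):
        theta1 = np.linspace(0.0, 30.0, 12)
        streams = synthesize_streams(mech_config, theta1, 0.0, np.arange(12.0))
        qs = {sid: q_normalize(
            streams[streams.sensor_id == sid][["qw", "qx", "qy", "qz"]].to_numpy())
            for sid in ("S1", "S2", "S3")}
        r12 = q_multiply(q_inverse(qs["S1"]), qs["S2"])
        r23 = q_multiply(q_inverse(qs["S2"]), qs["S3"])
        r13 = q_multiply(q_inverse(qs["S1"]), qs["S3"])
        assert np.abs(q_canonical(q_multiply(r12, r23)) - q_canonical(r13)).max() < 1e-9

    def test_no_overlap_rejected_and_gaps_flagged(self):
        rows = []
        for t in (0.0, 0.1, 1.0):  # a 0.9 s gap
            rows.append((t, "S1", 1.0, 0.0, 0.0, 0.0))
            rows.append((t, "S2", 1.0, 0.0, 0.0, 0.0))
        streams = pd.DataFrame(rows, columns=["time_s", "sensor_id",
                                              "qw", "qx", "qy", "qz"])
        series = joint_angle_series(streams, pairing={("S1", "S2"): 5})
        assert series[0].gap_flags.sum() == 1
        rows2 = streams.copy()
        rows2.loc[rows2.sensor_id == "S2", "time_s"] += 100.0
        with pytest.raises(ValueError, match="overlapping"):
            joint_angle_series(rows2, pairing={("S1", "S2"): 5})
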