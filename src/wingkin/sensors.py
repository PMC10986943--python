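"""Joint-angle extraction from inertial-sensor quaternion streams.

Four sensors ride on the steering gear (S1), humerus (S2), ulna (S3) and
metacarpal (S4).  For a sensor pair (a, b) the orientation of b in a's
frame at time t is ``p_ab(t) = p_a(t)^-1 (x) p_b(t)``; the joint motion is
the relative quaternion referenced to the start of the recording,

    p'_ab(t) = p_ab(t) (x) p_ab(0)^-1,

which is the identity at t = 0 and invariant under any rotation applied to
both sensors.  Joint angles are reported as intrinsic ZYX Euler angles
(yaw, pitch, roll) of p'_ab.

Quaternions are scalar-first ``(w, x, y, z)`` and multiplication follows
the Hamilton convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import matrix_to_euler_zyx

__all__ = [
    "SENSOR_JOINT_PAIRING",
    "q_multiply",
    "q_conjugate",
    "q_inverse",
    "q_normalize",
    "q_canonical",
    "q_angle_deg",
    "q_from_rotation",
    "q_to_matrix",
    "relative_quaternion",
    "quat_to_euler_zyx",
    "JointAngleSeries",
    "joint_angle_series",
    "synthesize_streams",
]

#: default (sensor_a, sensor_b) -> joint id mapping
SENSOR_JOINT_PAIRING = {("S1", "S2"): 5, ("S2", "S3"): 1, ("S3", "S4"): 2}

#: which bone each sensor rides on ("base" = fixed steering-gear bracket)
SENSOR_BONES = {"S1": "base", "S2": "humerus", "S3": "ulna", "S4": "metacarpal"}


def _as_quat(q) -> np.ndarray:
    q = np.asarray(q, float)
    if q.shape[-1] != 4:
        raise ValueError("quaternion must have 4 components (w, x, y, z)")
    return q


def q_normalize(q) -> np.ndarray:
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("zero-norm quaternion")
    return q / n


def q_multiply(a, b) -> np.ndarray:
    """Hamilton product a (x) b, scalar-first."""
    a, b = _as_quat(a), _as_quat(b)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def q_conjugate(q) -> np.ndarray:
    q = _as_quat(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def q_inverse(q) -> np.ndarray:
    return q_conjugate(q_normalize(q))


def q_canonical(q) -> np.ndarray:
    """Fix the double cover: flip sign so the scalar part is non-negative."""
    q = _as_quat(q)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign


def q_angle_deg(q) -> float | np.ndarray:
    """Total rotation angle of a unit quaternion, degrees, in [0, 180]."""
    q = q_canonical(q_normalize(q))
    ang = 2.0 * np.degrees(np.arctan2(np.linalg.norm(q[..., 1:], axis=-1), q[..., 0]))
    return float(ang) if np.isscalar(ang) or ang.ndim == 0 else ang


def q_from_rotation(rotation: Rotation) -> np.ndarray:
    return np.roll(rotation.as_quat(), 1, axis=-1)  # scipy is scalar-last


def q_to_matrix(q) -> np.ndarray:
    q = q_normalize(q)
    return Rotation.from_quat(np.roll(q, -1, axis=-1)).as_matrix()


def relative_quaternion(pa_t, pb_t, pa_0, pb_0) -> np.ndarray:
    """Motion of sensor b relative to sensor a since the reference time:
    ``(pa_t^-1 (x) pb_t) (x) (pa_0^-1 (x) pb_0)^-1``, normalised, scalar
    part made non-negative."""
    rel_t = q_multiply(q_inverse(pa_t), q_normalize(pb_t))
    rel_0 = q_multiply(q_inverse(pa_0), q_normalize(pb_0))
    out = q_multiply(rel_t, q_conjugate(rel_0))
    return q_canonical(q_normalize(out))


def quat_to_euler_zyx(q) -> np.ndarray:
    """(yaw, pitch, roll) in degrees of the intrinsic ZYX factorisation;
    yaw/roll in (-180, 180], pitch in [-90, 90]; roll = 0 at gimbal lock."""
    return matrix_to_euler_zyx(q_to_matrix(q_canonical(q)))


@dataclass
class JointAngleSeries:
    """Relative joint motion of one sensor pair over a common time grid."""

    joint_id: int
    sensor_pair: tuple[str, str]
    time_s: np.ndarray
    quaternions: np.ndarray          # (T, 4) relative quaternions, scalar-first
    euler_deg: pd.DataFrame          # columns yaw_deg, pitch_deg, roll_deg
    gap_flags: np.ndarray            # True where the sample gap exceeded 0.5 s

    @property
    def angle_deg(self) -> np.ndarray:
        """Total relative rotation angle per sample, degrees."""
        return q_angle_deg(self.quaternions)

    def extrema(self) -> dict:
        e = self.euler_deg
        return {c: {"min": float(e[c].min()), "max": float(e[c].max())} for c in e.columns}

    def to_frame(self) -> pd.DataFrame:
        df = self.euler_deg.copy()
        df.insert(0, "time_s", self.time_s)
        return df

    def plot(self, ax=None):
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        for c in self.euler_deg.columns:
            ax.plot(self.time_s, self.euler_deg[c], label=c.replace("_deg", ""))
        ax.set_xlabel("time (s)")
        ax.set_ylabel("angle (deg)")
        ax.set_title(f"joint {self.joint_id} ({self.sensor_pair[0]}-{self.sensor_pair[1]})")
        ax.legend()
        return ax


def _sensor_table(streams: pd.DataFrame, sensor: str):
    sub = streams[streams["sensor_id"] == sensor]
    if sub.empty:
        raise ValueError(f"no samples for sensor {sensor!r}")
    t = sub["time_s"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError(f"timestamps for sensor {sensor!r} are not sorted")
    q = q_normalize(sub[["qw", "qx", "qy", "qz"]].to_numpy(float))
    return t, q


def joint_angle_series(streams: pd.DataFrame,
                       pairing: dict[tuple[str, str], int] | None = None,
                       align_tol_s: float = 0.02,
                       gap_flag_s: float = 0.5) -> list[JointAngleSeries]:
    """Per-joint relative motion from a long-format quaternion stream table.

    ``streams`` has columns ``time_s, sensor_id, qw, qx, qy, qz``.  For each
    sensor pair the first sensor's time grid is the master; the partner's
    samples are matched by nearest timestamp within ``align_tol_s`` (no
    interpolation).  Gaps larger than ``gap_flag_s`` on the common grid are
    flagged.  Raises if the pair shares no overlapping window.
    """
    pairing = SENSOR_JOINT_PAIRING if pairing is None else pairing
    out = []
    for (sa, sb), joint_id in pairing.items():
        ta, qa = _sensor_table(streams, sa)
        tb, qb = _sensor_table(streams, sb)
        lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
        if lo > hi:
            raise ValueError(f"sensors {sa} and {sb} share no overlapping time window")
        mask = (ta >= lo - align_tol_s) & (ta <= hi + align_tol_s)
        t_grid = ta[mask]
        idx_b = np.clip(np.searchsorted(tb, t_grid), 0, len(tb) - 1)
        idx_b_prev = np.clip(idx_b - 1, 0, len(tb) - 1)
        pick_prev = np.abs(tb[idx_b_prev] - t_grid) < np.abs(tb[idx_b] - t_grid)
        idx_b = np.where(pick_prev, idx_b_prev, idx_b)
        ok = np.abs(tb[idx_b] - t_grid) <= align_tol_s
        t_grid, qa_m, qb_m = t_grid[ok], qa[mask][ok], qb[idx_b[ok]]
        if t_grid.size == 0:
            raise ValueError(f"no aligned samples for sensors {sa} and {sb} "
                             f"within {align_tol_s * 1e3:.0f} ms")
        rel = relative_quaternion(qa_m, qb_m, qa_m[0], qb_m[0])
        euler = np.array([quat_to_euler_zyx(q) for q in rel])
        gaps = np.concatenate([[False], np.diff(t_grid) > gap_flag_s])
        out.append(JointAngleSeries(
            joint_id=joint_id, sensor_pair=(sa, sb), time_s=t_grid,
            quaternions=rel,
            euler_deg=pd.DataFrame(euler, columns=["yaw_deg", "pitch_deg", "roll_deg"]),
            gap_flags=gaps))
    return out


def synthesize_streams(config, theta1_deg: np.ndarray, theta5_deg: np.ndarray | float = 0.0,
                       time_s: np.ndarray | None = None,
                       mounts: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Simulate sensor quaternion streams from the mechanism's forward
    kinematics over a stroke.

    Each sensor reports the orientation of its bone (times an optional
    constant mounting quaternion).  Returns a long-format DataFrame with
    columns ``time_s, sensor_id, qw, qx, qy, qz``.
    """
    from .mechanism import mechanism_forward

    theta1_deg = np.atleast_1d(np.asarray(theta1_deg, float))
    theta5_deg = np.broadcast_to(np.asarray(theta5_deg, float), theta1_deg.shape)
    if time_s is None:
        time_s = np.arange(len(theta1_deg), dtype=float)
    mounts = mounts or {}

    rows = []
    warm = None
    for t, th1, th5 in zip(time_s, theta1_deg, theta5_deg):
        state = mechanism_forward(config, float(th1), theta5=float(th5), warm_state=warm)
        warm = state
        for sensor, bone in SENSOR_BONES.items():
            if bone == "base":
                q = np.array([1.0, 0.0, 0.0, 0.0])
            else:
                q = q_from_rotation(Rotation.from_matrix(state.transforms[bone].matrix))
            if sensor in mounts:
                q = q_multiply(q, q_normalize(mounts[sensor]))
            q = q_canonical(q)
            rows.append((float(t), sensor, *q))
    return pd.DataFrame(rows, columns=["time_s", "sensor_id", "qw", "qx", "qy", "qz"])
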