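"""Rigid-body geometry primitives for skeletal pose analysis.

Conventions used throughout the package:

* rotations are intrinsic Z-Y-X Euler angles (yaw ``alpha`` about Z, then
  pitch ``beta`` about the rotated Y, then roll ``gamma`` about the rotated
  X), i.e. the rotation matrix is ``Rz(alpha) @ Ry(beta) @ Rx(gamma)``;
* angles are degrees at every public interface, lengths are millimetres;
* a rigid transform maps a point ``x`` to ``A @ x + t``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "Frame",
    "euler_zyx_to_matrix",
    "matrix_to_euler_zyx",
    "rotation_about_line",
    "build_global_frame",
    "bone_local_frame",
    "wrap_angle_deg",
]

_ORTHO_TOL = 1e-9


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into the interval (-180, 180]."""
    wrapped = -((-np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def euler_zyx_to_matrix(euler_deg) -> np.ndarray:
    """Rotation matrix of intrinsic ZYX Euler angles (yaw, pitch, roll) in degrees."""
    return Rotation.from_euler("ZYX", np.asarray(euler_deg, float), degrees=True).as_matrix()


def matrix_to_euler_zyx(matrix) -> np.ndarray:
    """Intrinsic ZYX Euler angles (degrees) of a rotation matrix.

    At gimbal lock (|pitch| = 90 deg) the roll angle is reported as zero.
    """
    matrix = np.asarray(matrix, float)
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; the zero-roll convention it applies is
        # exactly the one this package documents.
        warnings.simplefilter("ignore", UserWarning)
        ang = Rotation.from_matrix(matrix).as_euler("ZYX", degrees=True)
    return wrap_angle_deg(ang)


def _check_rotation(matrix: np.ndarray, tol: float = 1e-8) -> None:
    err = np.linalg.norm(matrix @ matrix.T - np.eye(3))
    if err > tol or np.linalg.det(matrix) < 0:
        raise ValueError(
            f"matrix is not a proper rotation (orthonormality error {err:.2e}, "
            f"det {np.linalg.det(matrix):.6f})"
        )


@dataclass(frozen=True)
class RigidTransform:
    """Rigid transform ``x -> A x + t`` with ZYX Euler parameterisation.

    Parameters
    ----------
    euler_zyx:
        (yaw, pitch, roll) in degrees.
    translation:
        3-vector in mm.
    """

    euler_zyx: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        e = wrap_angle_deg(np.asarray(self.euler_zyx, float).reshape(3))
        t = np.asarray(self.translation, float).reshape(3)
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(t))):
            raise ValueError("non-finite transform parameters")
        object.__setattr__(self, "euler_zyx", e)
        object.__setattr__(self, "translation", t)

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix, translation) -> "RigidTransform":
        matrix = np.asarray(matrix, float)
        _check_rotation(matrix)
        return cls(matrix_to_euler_zyx(matrix), np.asarray(translation, float))

    @classmethod
    def from_rotation(cls, rotation: Rotation, translation) -> "RigidTransform":
        return cls.from_matrix(rotation.as_matrix(), translation)

    # -- core operations -------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        return euler_zyx_to_matrix(self.euler_zyx)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of points."""
        pts = np.asarray(points, float)
        return pts @ self.matrix.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        a, b = self.matrix, other.matrix
        return RigidTransform.from_matrix(a @ b, a @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        a = self.matrix
        return RigidTransform.from_matrix(a.T, -a.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(np.degrees(np.linalg.norm(Rotation.from_matrix(self.matrix).as_rotvec())))

    def almost_equal(self, other: "RigidTransform", angle_tol_deg: float = 1e-6,
                     translation_tol: float = 1e-6) -> bool:
        dang = (self.inverse() @ other).rotation_angle_deg()
        dt = float(np.linalg.norm(self.translation - other.translation))
        return dang <= angle_tol_deg and dt <= translation_tol

    def as_dict(self) -> dict:
        return {
            "euler_deg": [float(v) for v in self.euler_zyx],
            "translation_mm": [float(v) for v in self.translation],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["euler_deg"], float), np.asarray(d["translation_mm"], float))


def rotation_about_line(point, axis, angle_deg: float) -> RigidTransform:
    """Rigid transform rotating by ``angle_deg`` about the line through ``point``
    with direction ``axis`` (need not be unit length)."""
    point = np.asarray(point, float)
    axis = np.asarray(axis, float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    rot = Rotation.from_rotvec(np.radians(angle_deg) * axis / n)
    mat = rot.as_matrix()
    return RigidTransform.from_matrix(mat, point - mat @ point)


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal frame: origin (mm) and axes as rows of a 3x3 matrix."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        origin = np.asarray(self.origin, float).reshape(3)
        axes = np.asarray(self.axes, float).reshape(3, 3)
        err = np.linalg.norm(axes @ axes.T - np.eye(3))
        if err > 1e-9:
            raise ValueError(f"frame axes not orthonormal (error {err:.2e})")
        if np.linalg.det(axes) < 0:
            raise ValueError("frame is left-handed")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.axes.T

    def to_global(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.axes + self.origin


def build_global_frame(humeral_head, metacarpal_proximal, up_hint=(0.0, 0.0, 1.0)) -> Frame:
    """Global wing frame: origin at the humeral head, X toward the proximal
    metacarpal head, Z the component of ``up_hint`` orthogonal to X, Y
    completing the right-handed triad."""
    head = np.asarray(humeral_head, float)
    meta = np.asarray(metacarpal_proximal, float)
    hint = np.asarray(up_hint, float)
    dx = meta - head
    nx = np.linalg.norm(dx)
    if nx < 1e-12:
        raise ValueError("landmarks coincide; cannot define the X axis")
    x = dx / nx
    z = hint - (hint @ x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("up hint is parallel to the landmark line")
    z = z / nz
    y = np.cross(z, x)
    return Frame(head, np.vstack([x, y, z]))


def _arclength_midpoint(polyline: np.ndarray):
    """Point at half the total arclength of a polyline, and the local tangent there."""
    p = np.asarray(polyline, float)
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] != 3:
        raise ValueError("centerline must be an (N>=2, 3) polyline")
    seg = np.diff(p, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    total = lens.sum()
    if total <= 0:
        raise ValueError("degenerate zero-length centerline")
    cum = np.concatenate([[0.0], np.cumsum(lens)])
    half = total / 2.0
    i = int(np.searchsorted(cum, half, side="right") - 1)
    i = min(i, len(lens) - 1)
    frac = (half - cum[i]) / lens[i] if lens[i] > 0 else 0.0
    mid = p[i] + frac * seg[i]
    tangent = seg[i] / lens[i]
    return mid, tangent


def bone_local_frame(centerline, global_frame: Frame) -> Frame:
    """Local bone frame: origin at the arclength midpoint of the centerline;
    X the midpoint tangent projected into the global XY plane; Z the global
    Z axis; Y completing the right-handed triad."""
    mid, tangent = _arclength_midpoint(np.asarray(centerline, float))
    gz = global_frame.z
    proj = tangent - (tangent @ gz) * gz
    n = np.linalg.norm(proj)
    if n < 1e-9:
        raise ValueError("centerline tangent is perpendicular to the global XY plane")
    x = proj / n
    y = np.cross(gz, x)
    return Frame(mid, np.vstack([x, y, gz]))
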