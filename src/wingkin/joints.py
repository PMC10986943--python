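"""Joint models and constraint algebra for the four-bar wing skeleton.

A joint couples two bones ``b`` (carrying axes ``u_b1``, ``u_b2``) and ``b'``
(carrying ``u_b3``).  For posture transforms ``T_b = (A_b, t_b)`` the
constraint sets are nested:

* ``ball``       — the shared center maps to the same point through both
                   bones: ``A_b c + t_b = A_b' c + t_b'``;
* ``universal``  — ball plus one preserved orthogonal pair:
                   ``(A_b u_b1) . (A_b' u_b3) = 0`` with ``u_b1 . u_b3 = 0``
                   in the reference posture;
* ``revolute``   — ball plus two preserved pairs with an orthonormal triad
                   ``u_b1, u_b2 _|_ u_b3``, i.e. the relative rotation keeps
                   the common axis ``u_b3`` fixed;
* ``unrestrained`` — no constraint (free 6-DOF joint).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform

__all__ = [
    "JOINT_TYPES",
    "JointSpec",
    "JointTopology",
    "DEFAULT_TOPOLOGY",
    "coincidence_violation",
    "axis_violations",
    "orthonormal_complement",
    "canonical_axis_sign",
    "estimate_center",
    "estimate_revolute_axis",
    "estimate_universal_axes",
    "relative_rotation",
    "revolute_angle_deg",
]

JOINT_TYPES = ("unrestrained", "ball", "universal", "revolute")

#: number of scalar axis constraints per joint type
AXIS_CONSTRAINT_COUNT = {"unrestrained": 0, "ball": 0, "universal": 1, "revolute": 2}


def _unit(v, name="axis") -> np.ndarray:
    v = np.asarray(v, float).reshape(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"zero-length {name}")
    return v / n


def orthonormal_complement(axis) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing ``axis`` to a right-handed orthonormal triad."""
    w = _unit(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = _unit(np.cross(helper, w))
    v = np.cross(w, u)
    return u, v


def canonical_axis_sign(axis) -> np.ndarray:
    """Normalise the sign of a direction: non-negative Z, ties to non-negative X."""
    a = _unit(axis)
    if a[2] < 0 or (a[2] == 0 and (a[0] < 0 or (a[0] == 0 and a[1] < 0))):
        return -a
    return a


@dataclass(frozen=True)
class JointSpec:
    """One joint of the wing chain.

    ``center`` is the shared rotation center in the reference global frame
    (mm); ``u_a1``/``u_a2`` are unit axes fixed in bone ``bone_a`` and
    ``u_b3`` a unit axis fixed in ``bone_b``, with the reference-posture
    orthogonality required by ``joint_type``.
    """

    joint_id: int
    bone_a: str
    bone_b: str
    joint_type: str
    center: np.ndarray
    u_a1: np.ndarray | None = None
    u_a2: np.ndarray | None = None
    u_b3: np.ndarray | None = None

    def __post_init__(self):
        if self.joint_type not in JOINT_TYPES:
            raise ValueError(f"unknown joint type {self.joint_type!r}")
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        for name in ("u_a1", "u_a2", "u_b3"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, _unit(v, name))
        if self.joint_type == "universal":
            if self.u_a1 is None or self.u_b3 is None:
                raise ValueError("universal joint needs u_a1 and u_b3")
            if abs(self.u_a1 @ self.u_b3) > 1e-9:
                raise ValueError("universal joint axes not orthogonal at reference")
        if self.joint_type == "revolute":
            if self.u_a1 is None or self.u_a2 is None or self.u_b3 is None:
                raise ValueError("revolute joint needs u_a1, u_a2 and u_b3")
            dots = (self.u_a1 @ self.u_b3, self.u_a2 @ self.u_b3, self.u_a1 @ self.u_a2)
            if max(abs(d) for d in dots) > 1e-9:
                raise ValueError("revolute joint triad not orthogonal at reference")

    @property
    def axis(self) -> np.ndarray | None:
        """The rotation axis for revolute joints (= ``u_b3``), else ``u_b3`` if set."""
        return self.u_b3

    def with_type(self, joint_type: str) -> "JointSpec":
        return replace(self, joint_type=joint_type)

    def as_dict(self) -> dict:
        d = {
            "joint_id": self.joint_id,
            "bones": [self.bone_a, self.bone_b],
            "type": self.joint_type,
            "center_mm": [float(v) for v in self.center],
        }
        for name in ("u_a1", "u_a2", "u_b3"):
            v = getattr(self, name)
            if v is not None:
                d[name] = [float(x) for x in v]
        return d


@dataclass(frozen=True)
class JointTopology:
    """Which bones each joint connects. The wing chain forms a closed loop."""

    pairs: tuple[tuple[int, str, str], ...]

    def bones(self) -> tuple[str, ...]:
        seen: list[str] = []
        for _, a, b in self.pairs:
            for bone in (a, b):
                if bone not in seen:
                    seen.append(bone)
        return tuple(seen)


#: elbow (1), wrist (2), distal radius (3) and proximal radius (4) joints
DEFAULT_TOPOLOGY = JointTopology(pairs=(
    (1, "humerus", "ulna"),
    (2, "ulna", "metacarpal"),
    (3, "radius", "metacarpal"),
    (4, "humerus", "radius"),
))


def coincidence_violation(joint: JointSpec, transform_a: RigidTransform,
                          transform_b: RigidTransform) -> float:
    """Distance (mm) between the joint center mapped through either bone."""
    pa = transform_a.apply(joint.center)
    pb = transform_b.apply(joint.center)
    return float(np.linalg.norm(pa - pb))


def axis_violations(joint: JointSpec, transform_a: RigidTransform,
                    transform_b: RigidTransform) -> list[float]:
    """Dimensionless axis-orthogonality defects for universal/revolute joints."""
    if joint.joint_type not in ("universal", "revolute"):
        raise ValueError(f"axis constraints undefined for a {joint.joint_type} joint")
    ra, rb = transform_a.matrix, transform_b.matrix
    u3 = rb @ joint.u_b3
    out = [float((ra @ joint.u_a1) @ u3)]
    if joint.joint_type == "revolute":
        out.append(float((ra @ joint.u_a2) @ u3))
    return out


# ---------------------------------------------------------------------------
# closed-form estimation of joint parameters from fitted bone transforms
# ---------------------------------------------------------------------------

def estimate_center(transform_pairs, init) -> np.ndarray:
    """Joint center minimising the summed squared coincidence violations.

    ``transform_pairs`` is an iterable of ``(T_a, T_b)`` over postures.  The
    normal system is rank-deficient for a hinge (any point of the axis is a
    center), so the minimal-norm correction about ``init`` is taken, which
    anchors the unidentifiable component at the initial guess.
    """
    init = np.asarray(init, float).reshape(3)
    m_rows, b_rows = [], []
    for ta, tb in transform_pairs:
        d = ta.matrix - tb.matrix
        m_rows.append(d)
        b_rows.append(-(d @ init) - (ta.translation - tb.translation))
    m = np.vstack(m_rows)
    b = np.concatenate(b_rows)
    delta, *_ = np.linalg.lstsq(m, b, rcond=1e-10)
    return init + delta


def relative_rotation(transform_a: RigidTransform, transform_b: RigidTransform) -> np.ndarray:
    """Rotation of bone b relative to bone a, expressed in bone a's frame."""
    return transform_a.matrix.T @ transform_b.matrix


def estimate_revolute_axis(relative_rotations) -> np.ndarray:
    """Common rotation axis of a set of relative rotations.

    The axis maximises ``sum_p u . R_p u``: the dominant eigenvector of
    ``sum_p (R_p + R_p^T)``.
    """
    s = np.zeros((3, 3))
    for r in relative_rotations:
        s += r + r.T
    w, v = np.linalg.eigh(s)
    return canonical_axis_sign(v[:, -1])


def estimate_universal_axes(relative_rotations, n_iter: int = 20):
    """Axis pair ``(u1, u3)`` with ``u1 . R_p u3 = 0`` for every relative
    rotation (including identity for the reference), in the least-squares
    sense.

    Alternating smallest-eigenvector updates from a few starts, followed by
    a Gauss-Newton polish on a minimal angle parameterisation.  With only
    two non-reference postures the consistent pairs form a one-parameter
    family; the returned pair is one exactly consistent member of it.
    """
    from scipy.optimize import least_squares

    rots = [np.eye(3)] + [np.asarray(r, float) for r in relative_rotations]

    def smallest(mat):
        w, v = np.linalg.eigh(mat)
        return v[:, 0]

    best = None
    # a couple of starts to dodge the alternation's local minima
    for seed_axis in (np.array([0., 0., 1.]), np.array([1., 0., 0.]), np.array([0., 1., 0.])):
        u3 = seed_axis.copy()
        for _ in range(n_iter):
            vs = np.array([r @ u3 for r in rots])
            u1 = smallest(vs.T @ vs)
            ws = np.array([r.T @ u1 for r in rots])
            u3 = smallest(ws.T @ ws)
        cost = sum(float(u1 @ r @ u3) ** 2 for r in rots)
        if best is None or cost < best[0]:
            best = (cost, u1, u3)
    _, u1, u3 = best

    def sph(u):
        return np.array([np.arccos(np.clip(u[2], -1, 1)), np.arctan2(u[1], u[0])])

    def unsph(a):
        th, ph = a
        return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])

    def resid(x):
        a1, a3 = unsph(x[:2]), unsph(x[2:])
        return np.array([a1 @ r @ a3 for r in rots])

    sol = least_squares(resid, np.concatenate([sph(u1), sph(u3)]),
                        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    u1, u3 = unsph(sol.x[:2]), unsph(sol.x[2:])
    u3 = canonical_axis_sign(u3)
    # re-orthogonalise the reference-posture pair exactly
    u1 = u1 - (u1 @ u3) * u3
    u1 = canonical_axis_sign(u1)
    return u1, u3


def revolute_angle_deg(joint: JointSpec, transform_a: RigidTransform,
                       transform_b: RigidTransform) -> float:
    """Signed rotation angle of bone b w.r.t. bone a about the joint axis, degrees."""
    if joint.u_b3 is None:
        raise ValueError("joint has no axis")
    rel = relative_rotation(transform_a, transform_b)
    rotvec = Rotation.from_matrix(rel).as_rotvec()
    return float(np.degrees(rotvec @ joint.u_b3))
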