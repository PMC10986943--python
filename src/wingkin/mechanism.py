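"""Forward kinematics of the 1-DOF four-bar wing skeleton.

The wing chain humerus-ulna-metacarpal-radius is modelled as a closed
spatial four-bar: the elbow (joint 1, humerus-ulna) and wrist (joint 2,
ulna-metacarpal) are revolute, the distal radius joint (joint 3,
radius-metacarpal) is universal and the proximal radius joint (joint 4,
humerus-radius) is a ball joint.  The ulna is the driving bar: its angle
``theta1`` about the elbow axis determines the wrist angle ``theta2``
through a monotone coupling law anchored at the measured postures, and the
radius follows as the closing link.  A shoulder pitch joint (joint 5)
rotates the whole assembly within +/-30 degrees.

The default geometry places the ball-joint center on the elbow axis and the
universal-joint center on the wrist axis.  Then the radius link length is
invariant under any (theta1, theta2) pair, so the loop closes exactly along
the entire stroke for the anchored coupling law; the remaining spin of the
radius about its chord is fixed by the universal joint's preserved
orthogonal axis pair, solved by damped Gauss-Newton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cloud import BONES, BoneCloud
from .geometry import RigidTransform, rotation_about_line
from .joints import (DEFAULT_TOPOLOGY, JointSpec, axis_violations,
                     coincidence_violation, orthonormal_complement)

__all__ = [
    "DEFAULT_ANCHORS",
    "WingGeometry",
    "MechanismConfig",
    "MechanismState",
    "MechanismClosureError",
    "coupling_law",
    "default_config",
    "mechanism_forward",
    "reproduce_postures",
]

#: (theta1, theta2) coupling anchors, degrees: full extension, half
#: extension and full contraction of the elbow/wrist pair.
DEFAULT_ANCHORS = np.array([[0.0, 0.0], [15.54, 22.84], [37.18, 55.65]])

_COINCIDENCE_TOL = 1e-6   # mm
_AXIS_TOL = 1e-9          # dimensionless


class MechanismClosureError(RuntimeError):
    """Raised when the four-bar loop cannot be closed at the requested angles."""


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class WingGeometry:
    """Node points and joint axes of the wing chain in the reference
    (fully extended) global frame, mm.

    The proximal radius attachment sits on the elbow axis at offset
    ``radius_proximal_offset`` from the elbow center, the distal attachment
    on the wrist axis at offset ``radius_distal_offset`` from the wrist
    center; see the module docstring for why.
    """

    shoulder: np.ndarray = field(default_factory=lambda: np.zeros(3))
    elbow: np.ndarray = field(default_factory=lambda: np.array([58.0, -10.0, 2.0]))
    wrist: np.ndarray = field(default_factory=lambda: np.array([120.0, -18.0, 4.0]))
    wing_tip: np.ndarray = field(default_factory=lambda: np.array([154.0, -20.0, 5.0]))
    elbow_axis: np.ndarray = field(default_factory=lambda: _unit([-0.10, -0.08, 0.99]))
    wrist_axis: np.ndarray = field(default_factory=lambda: _unit([-0.02, -0.52, 0.85]))
    radius_proximal_offset: float = 5.0
    radius_distal_offset: float = -4.0

    def __post_init__(self):
        for name in ("shoulder", "elbow", "wrist", "wing_tip"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        object.__setattr__(self, "elbow_axis", _unit(self.elbow_axis))
        object.__setattr__(self, "wrist_axis", _unit(self.wrist_axis))

    @property
    def radius_proximal(self) -> np.ndarray:
        """Ball-joint (joint 4) center: on the elbow axis."""
        return self.elbow + self.radius_proximal_offset * self.elbow_axis

    @property
    def radius_distal(self) -> np.ndarray:
        """Universal-joint (joint 3) center: on the wrist axis."""
        return self.wrist + self.radius_distal_offset * self.wrist_axis

    def joint_specs(self) -> dict[int, JointSpec]:
        """Ground-truth joint specs of the 1-DOF mechanism."""
        u1, u2 = orthonormal_complement(self.elbow_axis)
        j1 = JointSpec(1, "humerus", "ulna", "revolute", self.elbow,
                       u_a1=u1, u_a2=u2, u_b3=self.elbow_axis)
        v1, v2 = orthonormal_complement(self.wrist_axis)
        j2 = JointSpec(2, "ulna", "metacarpal", "revolute", self.wrist,
                       u_a1=v1, u_a2=v2, u_b3=self.wrist_axis)
        chord = _unit(self.radius_distal - self.radius_proximal)
        z = np.array([0.0, 0.0, 1.0])
        u_r1 = _unit(z - (z @ chord) * chord)       # fixed in the radius
        u_m3 = _unit(np.cross(chord, u_r1))          # fixed in the metacarpal
        j3 = JointSpec(3, "radius", "metacarpal", "universal", self.radius_distal,
                       u_a1=u_r1, u_b3=u_m3)
        j4 = JointSpec(4, "humerus", "radius", "ball", self.radius_proximal)
        return {1: j1, 2: j2, 3: j3, 4: j4}

    def bone_endpoints(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        return {
            "humerus": (self.shoulder, self.elbow),
            "ulna": (self.elbow, self.wrist),
            "radius": (self.radius_proximal, self.radius_distal),
            "metacarpal": (self.wrist, self.wing_tip),
        }


@dataclass(frozen=True)
class MechanismConfig:
    """Four-bar mechanism: geometry, joint specs, coupling anchors and the
    shoulder pitch (joint 5) range."""

    geometry: WingGeometry
    joints: dict[int, JointSpec]
    coupling_anchors: np.ndarray = field(default_factory=lambda: DEFAULT_ANCHORS.copy())
    pitch_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    pitch_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pitch_range_deg: tuple[float, float] = (-30.0, 30.0)

    def __post_init__(self):
        anchors = np.asarray(self.coupling_anchors, float)
        if anchors.ndim != 2 or anchors.shape[1] != 2:
            raise ValueError("anchors must be an (N, 2) array of (theta1, theta2)")
        if np.any(np.diff(anchors[:, 0]) <= 0):
            raise ValueError("anchor theta1 values must be strictly increasing")
        object.__setattr__(self, "coupling_anchors", anchors)
        object.__setattr__(self, "pitch_axis", _unit(self.pitch_axis))
        object.__setattr__(self, "pitch_point", np.asarray(self.pitch_point, float).reshape(3))

    @property
    def theta1_max(self) -> float:
        return float(self.coupling_anchors[-1, 0])


def default_config() -> MechanismConfig:
    geom = WingGeometry()
    return MechanismConfig(geometry=geom, joints=geom.joint_specs())


def coupling_law(theta1: float, anchors: np.ndarray | None = None) -> float:
    """Wrist angle theta2 (deg) coupled to the elbow angle theta1 (deg):
    piecewise-linear interpolation through the posture anchors."""
    anchors = DEFAULT_ANCHORS if anchors is None else np.asarray(anchors, float)
    t1 = float(theta1)
    lo, hi = anchors[0, 0], anchors[-1, 0]
    if not (lo - 1e-9 <= t1 <= hi + 1e-9):
        raise ValueError(f"theta1={t1:g} outside the coupling range [{lo:g}, {hi:g}] deg")
    return float(np.interp(np.clip(t1, lo, hi), anchors[:, 0], anchors[:, 1]))


@dataclass(frozen=True)
class MechanismState:
    """Solved configuration of the mechanism at one drive angle."""

    theta1: float
    theta2: float
    theta5: float
    transforms: dict[str, RigidTransform]
    closure_residual_mm: float
    max_coincidence_mm: float
    max_axis_dot: float

    def transform(self, bone_id: str) -> RigidTransform:
        return self.transforms[bone_id]

    def as_dict(self) -> dict:
        return {
            "theta1_deg": self.theta1,
            "theta2_deg": self.theta2,
            "theta5_deg": self.theta5,
            "transforms": {b: t.as_dict() for b, t in self.transforms.items()},
            "closure_residual_mm": self.closure_residual_mm,
        }


def _solve_radius(config: MechanismConfig, t_metacarpal: RigidTransform,
                  warm_rotvec: np.ndarray | None):
    """Rotation of the radius about the ball joint closing joints 3 and 4."""
    j3, j4 = config.joints[3], config.joints[4]
    c4 = j4.center
    d0 = j3.center - c4
    target = t_metacarpal.apply(j3.center) - c4
    scale = np.linalg.norm(d0)
    u_r1 = j3.u_a1
    u_m3_now = t_metacarpal.matrix @ j3.u_b3

    def resid(p):
        rot = Rotation.from_rotvec(p).as_matrix()
        out = np.empty(4)
        out[:3] = rot @ d0 - target
        out[3] = scale * ((rot @ u_r1) @ u_m3_now)
        return out

    p0 = np.zeros(3) if warm_rotvec is None else np.asarray(warm_rotvec, float)
    sol = least_squares(resid, p0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if np.linalg.norm(sol.fun) > 1e-4 and warm_rotvec is not None:
        # retry from scratch if the warm start led to a bad branch
        sol = least_squares(resid, np.zeros(3), method="lm",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
    rot = Rotation.from_rotvec(sol.x).as_matrix()
    t_radius = RigidTransform.from_matrix(rot, c4 - rot @ c4)
    return t_radius, float(np.linalg.norm(sol.fun)), sol.x


def _state_violations(config: MechanismConfig, transforms: dict[str, RigidTransform]):
    max_c, max_a = 0.0, 0.0
    for joint in config.joints.values():
        ta, tb = transforms[joint.bone_a], transforms[joint.bone_b]
        max_c = max(max_c, coincidence_violation(joint, ta, tb))
        if joint.joint_type in ("universal", "revolute"):
            max_a = max(max_a, max(abs(v) for v in axis_violations(joint, ta, tb)))
    return max_c, max_a


def mechanism_forward(config: MechanismConfig, theta1: float, theta5: float = 0.0,
                      theta2: float | None = None,
                      warm_state: MechanismState | None = None) -> MechanismState:
    """Solve the mechanism at drive angle ``theta1`` (deg) and shoulder pitch
    ``theta5`` (deg).

    ``theta2`` defaults to the coupling law; passing it explicitly poses the
    wrist off the coupling curve (used e.g. to study mis-matched coupling).
    Raises :class:`MechanismClosureError` if the loop cannot be closed to
    tolerance.
    """
    lo, hi = config.pitch_range_deg
    if not (lo - 1e-9 <= theta5 <= hi + 1e-9):
        raise ValueError(f"theta5={theta5:g} outside pitch range [{lo:g}, {hi:g}] deg")
    if theta2 is None:
        theta2 = coupling_law(theta1, config.coupling_anchors)

    j1, j2 = config.joints[1], config.joints[2]
    t_humerus = RigidTransform.identity()
    t_ulna = rotation_about_line(j1.center, j1.u_b3, theta1)
    t_meta = t_ulna @ rotation_about_line(j2.center, j2.u_b3, theta2)

    warm = None
    if warm_state is not None:
        rel = warm_state.transforms["radius"].matrix
        warm = Rotation.from_matrix(rel).as_rotvec()
    t_radius, closure, _ = _solve_radius(config, t_meta, warm)

    transforms = {"humerus": t_humerus, "ulna": t_ulna,
                  "radius": t_radius, "metacarpal": t_meta}
    if theta5 != 0.0:
        pitch = rotation_about_line(config.pitch_point, config.pitch_axis, theta5)
        transforms = {b: pitch @ t for b, t in transforms.items()}

    max_c, max_a = _state_violations(config, transforms)
    if max_c > _COINCIDENCE_TOL or max_a > _AXIS_TOL:
        raise MechanismClosureError(
            f"loop closure failed at theta1={theta1:g}, theta2={theta2:g} deg: "
            f"coincidence {max_c:.3e} mm, axis dot {max_a:.3e} "
            f"(closure residual norm {closure:.3e})")
    return MechanismState(theta1=float(theta1), theta2=float(theta2),
                          theta5=float(theta5), transforms=transforms,
                          closure_residual_mm=closure,
                          max_coincidence_mm=max_c, max_axis_dot=max_a)


def reproduce_postures(config: MechanismConfig,
                       reference_clouds: dict[str, BoneCloud],
                       posture_clouds: dict[str, dict[str, BoneCloud]],
                       downsample: int = 2000, seed: int = 0,
                       xatol_deg: float = 1e-4):
    """Best 1-DOF reproduction of measured postures.

    For each posture, the drive angle minimising the mean one-sided
    nearest-neighbour residual between the mechanism-posed reference clouds
    and the posture clouds is found by bounded scalar minimisation.

    Returns ``(residual_table, theta1_by_posture)`` where the table is a
    DataFrame of per-bone residuals (mm) indexed by posture.
    """
    bones = [b for b in BONES if b in reference_clouds]
    trees = {}
    for b in bones:
        ds = reference_clouds[b].subsample(downsample, seed=seed)
        trees[b] = (cKDTree(ds.points), ds.points)

    def per_bone_residuals(theta1, clouds, state_cache=[None]):
        state = mechanism_forward(config, theta1, warm_state=state_cache[0])
        state_cache[0] = state
        out = {}
        for b in bones:
            t = state.transforms[b]
            back = (clouds[b].points - t.translation) @ t.matrix
            d, _ = trees[b][0].query(back, k=1)
            out[b] = float(np.mean(d))
        return out, state

    rows = {}
    theta_by_posture = {}
    for posture, clouds in posture_clouds.items():
        def objective(theta1, clouds=clouds):
            vals, _ = per_bone_residuals(theta1, clouds)
            return float(np.mean(list(vals.values())))

        res = minimize_scalar(objective, bounds=(0.0, config.theta1_max),
                              method="bounded", options={"xatol": xatol_deg})
        theta_by_posture[posture] = float(res.x)
        vals, _ = per_bone_residuals(res.x, clouds)
        rows[posture] = vals

    table = pd.DataFrame.from_dict(rows, orient="index")[bones]
    table.index.name = "posture"
    return table, theta_by_posture
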