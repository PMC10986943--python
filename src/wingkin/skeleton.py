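"""Synthetic articulated wing-skeleton generator.

Real input data for this pipeline are segmented CT point clouds of the four
main wing bones in several postures.  This module generates a stand-in with
known ground truth: each bone is a bent-tube surface with hemispherical end
caps and a few hemispheric bumps (so the shape has no rotational symmetry
and its rigid pose is uniquely recoverable), laid out along the default
four-bar wing geometry and posed by the mechanism's forward kinematics.
Isotropic Gaussian point noise emulates segmentation error.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import BONES, POSTURES, BoneCloud
from .geometry import RigidTransform
from .joints import JointSpec
from .mechanism import (MechanismClosureError, MechanismConfig, WingGeometry,
                        coupling_law, default_config, mechanism_forward)

__all__ = [
    "Bump",
    "BoneShapeSpec",
    "SkeletonTruth",
    "PosedSkeletonDataset",
    "make_bone_cloud",
    "default_shape_specs",
    "default_skeleton",
    "pose_skeleton",
]


@dataclass(frozen=True)
class Bump:
    """Hemispheric surface bump: arclength fraction ``s`` in [0, 1], angular
    position ``phi`` (rad) around the tube, outward amplitude (mm)."""

    s: float
    phi: float
    amplitude: float
    s_width: float = 0.07
    phi_width: float = 0.6


@dataclass(frozen=True)
class BoneShapeSpec:
    """Shape of one synthetic bone (canonical frame: chord along +X)."""

    bone_id: str
    length: float
    radius_profile: tuple[float, ...] = (2.5, 2.0, 2.4)
    bend: float = 2.0
    n_points: int = 2000
    asymmetry_features: tuple[Bump, ...] = (Bump(0.2, 0.8, 1.5), Bump(0.7, 3.6, 1.2))

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("bone length must be positive")
        if self.n_points < 50:
            raise ValueError("n_points must be >= 50")
        if len(self.radius_profile) < 1 or min(self.radius_profile) <= 0:
            raise ValueError("radius profile must contain positive radii")
        if len(self.asymmetry_features) < 1:
            raise ValueError("at least one asymmetry feature is required "
                             "(a plain tube has a rotational symmetry axis)")


def _canonical_centerline(spec: BoneShapeSpec, s: np.ndarray) -> np.ndarray:
    # chord along +X from 0 to length; parabolic bow of height `bend` in +Y
    x = s * spec.length
    y = spec.bend * 4.0 * s * (1.0 - s)
    return np.column_stack([x, y, np.zeros_like(x)])


def _tube_frames(spec: BoneShapeSpec, s: np.ndarray):
    dyds = spec.bend * 4.0 * (1.0 - 2.0 * s)
    t = np.column_stack([np.full_like(s, spec.length), dyds, np.zeros_like(s)])
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    z = np.array([0.0, 0.0, 1.0])
    n1 = z - t * (t @ z)[:, None]
    n1 /= np.linalg.norm(n1, axis=1, keepdims=True)
    n2 = np.cross(t, n1)
    return t, n1, n2


def _surface_radius(spec: BoneShapeSpec, s: np.ndarray, phi: np.ndarray) -> np.ndarray:
    knots = np.linspace(0.0, 1.0, len(spec.radius_profile))
    r = np.interp(s, knots, spec.radius_profile)
    for bump in spec.asymmetry_features:
        dphi = np.angle(np.exp(1j * (phi - bump.phi)))
        r = r + bump.amplitude * np.exp(-0.5 * ((s - bump.s) / bump.s_width) ** 2
                                        - 0.5 * (dphi / bump.phi_width) ** 2)
    return r


def make_bone_cloud(spec: BoneShapeSpec, seed: int) -> BoneCloud:
    """Sample ``spec.n_points`` points on the bone surface (canonical frame).

    Roughly 90% of the points lie on the bumpy bent tube, the rest on the two
    hemispherical end caps (the bone "heads"); the two chord-end rings are
    always sampled so the cloud spans the full length.
    """
    rng = np.random.default_rng(seed)
    n_cap = max(4, spec.n_points // 12)
    n_tube = spec.n_points - 2 * n_cap

    s = np.concatenate([[0.0, 1.0], rng.uniform(0.0, 1.0, n_tube - 2)])
    phi = rng.uniform(0.0, 2.0 * np.pi, n_tube)
    c = _canonical_centerline(spec, s)
    _, n1, n2 = _tube_frames(spec, s)
    r = _surface_radius(spec, s, phi)
    tube = c + r[:, None] * (np.cos(phi)[:, None] * n2 + np.sin(phi)[:, None] * n1)

    caps = []
    for s_end, sign in ((0.0, -1.0), (1.0, 1.0)):
        center = _canonical_centerline(spec, np.array([s_end]))[0]
        t_end, _, _ = _tube_frames(spec, np.array([s_end]))
        t_end = sign * t_end[0]
        dirs = rng.normal(size=(n_cap, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        dots = dirs @ t_end
        dirs[dots < 0] -= 2.0 * dots[dots < 0, None] * t_end  # fold onto outward hemisphere
        r_end = _surface_radius(spec, np.full(n_cap, s_end), np.zeros(n_cap))
        caps.append(center + r_end[:, None] * dirs)

    points = np.vstack([tube] + caps)
    centerline = _canonical_centerline(spec, np.linspace(0.0, 1.0, 41))
    return BoneCloud(points=points, centerline=centerline,
                     bone_id=spec.bone_id, posture_id="canonical")


def default_shape_specs(geometry: WingGeometry | None = None,
                        n_points: int = 2000) -> dict[str, BoneShapeSpec]:
    """Shape specs at the falcon's scale, chord lengths taken from the wing
    geometry (humerus ~59 mm, ulna ~63 mm, radius ~63 mm, metacarpal ~34 mm)."""
    geom = geometry or WingGeometry()
    ends = geom.bone_endpoints()
    lengths = {b: float(np.linalg.norm(p1 - p0)) for b, (p0, p1) in ends.items()}
    return {
        "humerus": BoneShapeSpec(
            "humerus", lengths["humerus"], (3.5, 2.6, 3.1), 2.5, n_points,
            (Bump(0.18, 0.5, 1.8), Bump(0.55, 2.4, 1.4), Bump(0.82, 4.4, 1.6))),
        "ulna": BoneShapeSpec(
            "ulna", lengths["ulna"], (2.6, 2.1, 2.4), 3.0, n_points,
            (Bump(0.15, 1.2, 1.5), Bump(0.50, 3.5, 1.2), Bump(0.85, 5.5, 1.4))),
        "radius": BoneShapeSpec(
            "radius", lengths["radius"], (1.6, 1.3, 1.5), -2.0, n_points,
            (Bump(0.20, 0.8, 1.0), Bump(0.60, 2.9, 0.9), Bump(0.90, 5.0, 1.0))),
        "metacarpal": BoneShapeSpec(
            "metacarpal", lengths["metacarpal"], (2.2, 1.6, 1.2), 1.2, n_points,
            (Bump(0.25, 1.5, 1.2), Bump(0.70, 4.0, 1.0))),
    }


def _placement(p_start: np.ndarray, p_end: np.ndarray) -> RigidTransform:
    """Map the canonical chord (0..L along X, bow in the XY plane) onto the
    segment p_start -> p_end, keeping the canonical Z as close to global Z
    as possible (all bones bow roughly within the wing plane)."""
    d = p_end - p_start
    x = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    z = z - (z @ x) * x
    z /= np.linalg.norm(z)
    y = np.cross(z, x)
    rot = np.column_stack([x, y, z])
    return RigidTransform.from_matrix(rot, p_start)


@dataclass(frozen=True)
class SkeletonTruth:
    """Reference-posture skeleton with full ground truth.

    Reference clouds are in the global frame with the humerus (and every
    bone) at identity; joint specs hold the true centers/axes of the four
    joints; landmarks give the humeral head and proximal metacarpal head
    used for global-frame construction.  Study counts: ``n_b = 4`` bones,
    ``n_j = 4`` joints; postures are chosen at pose time (default 3).
    """

    config: MechanismConfig
    shape_specs: dict[str, BoneShapeSpec]
    reference_clouds: dict[str, BoneCloud]
    joints: dict[int, JointSpec]
    landmarks: dict[str, np.ndarray]
    seed: int

    @property
    def geometry(self) -> WingGeometry:
        return self.config.geometry

    @property
    def n_bones(self) -> int:
        return len(self.reference_clouds)

    @property
    def n_joints(self) -> int:
        return len(self.joints)


def default_skeleton(seed: int = 0, n_points: int = 2000,
                     geometry: WingGeometry | None = None,
                     config: MechanismConfig | None = None) -> SkeletonTruth:
    """Generate the default synthetic skeleton in the reference posture."""
    if config is None:
        geom = geometry or WingGeometry()
        config = MechanismConfig(geometry=geom, joints=geom.joint_specs())
    geom = config.geometry
    specs = default_shape_specs(geom, n_points=n_points)
    ends = geom.bone_endpoints()
    clouds = {}
    for i, bone in enumerate(BONES):
        canonical = make_bone_cloud(specs[bone], seed=seed * 101 + i)
        place = _placement(*ends[bone])
        placed = canonical.transformed(place)
        clouds[bone] = BoneCloud(points=placed.points, centerline=placed.centerline,
                                 bone_id=bone, posture_id=POSTURES[0])
    landmarks = {"humeral_head": geom.shoulder.copy(),
                 "metacarpal_proximal": geom.wrist.copy()}
    return SkeletonTruth(config=config, shape_specs=specs, reference_clouds=clouds,
                         joints=config.joints, landmarks=landmarks, seed=seed)


@dataclass(frozen=True)
class PosedSkeletonDataset:
    """Posed (and optionally noisy) clouds plus the generating ground truth."""

    truth: SkeletonTruth
    postures: tuple[str, ...]
    clouds: dict[str, dict[str, BoneCloud]]
    noiseless: dict[str, dict[str, BoneCloud]]
    transforms: dict[str, dict[str, RigidTransform]]
    angles: dict[str, tuple[float, float]]
    noise_sd: float
    seed: int

    @property
    def reference(self) -> dict[str, BoneCloud]:
        return self.truth.reference_clouds

    @property
    def non_reference_postures(self) -> tuple[str, ...]:
        return tuple(p for p in self.postures if p != POSTURES[0])


def pose_skeleton(truth: SkeletonTruth, angles=None, noise_sd: float = 0.3,
                  seed: int = 0) -> PosedSkeletonDataset:
    """Pose the skeleton into the study postures and add point noise.

    Parameters
    ----------
    angles:
        mapping posture name -> drive angle ``theta1`` (deg) or pair
        ``(theta1, theta2)``; defaults to the three scanned postures at the
        coupling anchors (0, 15.54, 37.18 deg).  ``theta2`` defaults to the
        coupling law.
    noise_sd:
        isotropic Gaussian point noise (mm), applied after posing.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if angles is None:
        anchors = truth.config.coupling_anchors
        angles = {p: tuple(anchors[i]) for i, p in enumerate(POSTURES)}

    rng = np.random.default_rng(seed)
    clouds, clean, transforms, used_angles = {}, {}, {}, {}
    for posture, ang in angles.items():
        theta1, theta2 = (ang if np.iterable(ang) else (float(ang), None))
        try:
            state = mechanism_forward(truth.config, float(theta1), theta2=theta2)
        except (ValueError, MechanismClosureError) as err:
            raise MechanismClosureError(
                f"posture {posture!r} is infeasible: {err}") from err
        used_angles[posture] = (state.theta1, state.theta2)
        transforms[posture] = dict(state.transforms)
        clean[posture] = {}
        clouds[posture] = {}
        for bone, ref in truth.reference_clouds.items():
            posed = ref.transformed(state.transforms[bone])
            posed = BoneCloud(points=posed.points, centerline=posed.centerline,
                              bone_id=bone, posture_id=posture)
            clean[posture][bone] = posed
            noisy_pts = posed.points
            if noise_sd > 0:
                noisy_pts = noisy_pts + rng.normal(0.0, noise_sd, posed.points.shape)
            clouds[posture][bone] = BoneCloud(points=noisy_pts, centerline=posed.centerline,
                                              bone_id=bone, posture_id=posture)
    return PosedSkeletonDataset(truth=truth, postures=tuple(angles), clouds=clouds,
                                noiseless=clean, transforms=transforms,
                                angles=used_angles, noise_sd=float(noise_sd), seed=seed)
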