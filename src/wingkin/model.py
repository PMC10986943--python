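"""Joint-constrained skeleton fitting: model and results objects.

:class:`SkeletonPoseModel` holds the reference (full-extension) clouds and
the posture clouds of the four-bone wing chain.  ``fit()`` estimates one
rigid transform per bone per non-reference posture — unconstrained, or
subject to the joint constraint sets of a chosen four-bar model (ball /
universal / revolute per joint) — and returns a
:class:`SkeletonFitResults` carrying the transforms, the estimated joint
centers and axes, the residual table and the constraint violations.

The constrained optimisation minimises the mean one-sided nearest-neighbour
residual over all bones and postures subject to, for every non-reference
posture and every joint, the center-coincidence equation and the
axis-orthogonality equations of the joint's type.  It proceeds in three
stages: (1) per-bone unconstrained multi-start fits; (2) quadratic-penalty
refinement (weight x10 per round) by blockwise Nelder-Mead over each bone's
six pose parameters, re-estimating joint centers/axes in closed form
between sweeps; (3) a feasibility polish — Gauss-Newton least squares on
the violation residuals over all transforms and joint parameters — so the
returned solution satisfies the active constraints to tight tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize
from scipy.spatial import cKDTree

from .cloud import BONES, BoneCloud
from .geometry import RigidTransform, euler_zyx_to_matrix
from .joints import (DEFAULT_TOPOLOGY, JointSpec, JointTopology,
                     axis_violations, canonical_axis_sign,
                     coincidence_violation, estimate_center,
                     estimate_revolute_axis, estimate_universal_axes,
                     orthonormal_complement, relative_rotation,
                     revolute_angle_deg)
from .registration import FitOptions, PoseFit, fit_pose_unconstrained, mean_residual

__all__ = [
    "MODEL_PRESETS",
    "ConstrainedFitOptions",
    "SkeletonPoseModel",
    "SkeletonFitResults",
    "ModelComparison",
    "fit_skeleton_constrained",
    "compare_joint_models",
]

#: named joint-type assignments (joint id -> type)
MODEL_PRESETS = {
    "unrestrained": {1: "unrestrained", 2: "unrestrained", 3: "unrestrained", 4: "unrestrained"},
    "ball": {1: "ball", 2: "ball", 3: "ball", 4: "ball"},
    "universal": {1: "universal", 2: "universal", 3: "universal", 4: "universal"},
    "revolute": {1: "revolute", 2: "revolute", 3: "revolute", 4: "revolute"},
    "onedof": {1: "revolute", 2: "revolute", 3: "universal", 4: "ball"},
}

_STRICTNESS = {"unrestrained": 0, "ball": 1, "universal": 2, "revolute": 3}


def _nested(types_loose: dict, types_tight: dict) -> bool:
    """True if every joint of ``types_tight`` is at least as constrained."""
    return all(_STRICTNESS[types_tight[j]] >= _STRICTNESS[t]
               for j, t in types_loose.items())


@dataclass(frozen=True)
class ConstrainedFitOptions:
    """Options for the penalty + polish constrained fit."""

    pose_options: FitOptions = field(default_factory=FitOptions)
    penalty_mu0: float = 10.0
    penalty_factor: float = 10.0
    penalty_rounds: int = 4
    sweeps_per_round: int = 2
    block_maxfev: int = 200
    length_scale_mm: float = 50.0
    coincidence_tol_mm: float = 1e-4
    axis_tol: float = 1e-6


# ---------------------------------------------------------------------------
# axis parameterisation for the feasibility polish (unit norm kept exactly)
# ---------------------------------------------------------------------------

def _axis_to_spherical(u: np.ndarray) -> np.ndarray:
    return np.array([np.arccos(np.clip(u[2], -1.0, 1.0)), np.arctan2(u[1], u[0])])


def _spherical_to_axis(sph: np.ndarray) -> np.ndarray:
    th, ph = sph
    return np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])


def _joint_from_params(joint: JointSpec, center: np.ndarray,
                       axis_params: np.ndarray | None) -> JointSpec:
    if joint.joint_type in ("unrestrained", "ball") or axis_params is None:
        return replace(joint, center=center)
    u3 = _spherical_to_axis(axis_params[:2])
    e1, e2 = orthonormal_complement(u3)
    if joint.joint_type == "revolute":
        return replace(joint, center=center, u_a1=e1, u_a2=e2, u_b3=u3)
    psi = axis_params[2]
    u1 = np.cos(psi) * e1 + np.sin(psi) * e2
    return replace(joint, center=center, u_a1=u1, u_a2=None, u_b3=u3)


def _joint_axis_params(joint: JointSpec) -> np.ndarray | None:
    if joint.joint_type in ("unrestrained", "ball"):
        return None
    sph = _axis_to_spherical(joint.u_b3)
    if joint.joint_type == "revolute":
        return sph
    e1, e2 = orthonormal_complement(joint.u_b3)
    psi = np.arctan2(joint.u_a1 @ e2, joint.u_a1 @ e1)
    return np.concatenate([sph, [psi]])


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class SkeletonFitResults:
    """Fitted bone transforms, joint estimates and diagnostics."""

    joint_types: dict[int, str]
    transforms: dict[str, dict[str, RigidTransform]]
    joints: dict[int, JointSpec] | None
    residual_table: pd.DataFrame
    base_fits: dict[tuple[str, str], PoseFit]
    max_coincidence_mm: float
    max_axis_dot: float
    status: str
    model: "SkeletonPoseModel | None" = None

    @property
    def mean_residual_mm(self) -> float:
        return mean_residual(self.residual_table)

    @property
    def is_constrained(self) -> bool:
        return any(t != "unrestrained" for t in self.joint_types.values())

    def transform(self, posture: str, bone: str) -> RigidTransform:
        return self.transforms[posture][bone]

    def joint_angles_deg(self) -> pd.DataFrame:
        """Relative joint rotation per posture, degrees.

        For revolute joints the signed angle about the fitted axis; for
        other joints the total relative rotation magnitude.
        """
        if self.joints is None:
            raise ValueError("unconstrained fits carry no joint estimates")
        from scipy.spatial.transform import Rotation
        rows = {}
        for jid, joint in self.joints.items():
            row = {}
            for posture, tf in self.transforms.items():
                ta, tb = tf[joint.bone_a], tf[joint.bone_b]
                if joint.joint_type == "revolute":
                    row[posture] = revolute_angle_deg(joint, ta, tb)
                else:
                    rel = relative_rotation(ta, tb)
                    row[posture] = float(np.degrees(
                        np.linalg.norm(Rotation.from_matrix(rel).as_rotvec())))
            rows[jid] = row
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "joint"
        return df

    def table1_view(self) -> pd.DataFrame:
        """Residual table restricted to the bones conventionally printed
        (ulna, humerus, metacarpal)."""
        cols = [b for b in ("ulna", "humerus", "metacarpal")
                if b in self.residual_table.columns]
        return self.residual_table[cols]

    def summary(self) -> str:
        lines = []
        types = ", ".join(f"J{j}:{t}" for j, t in sorted(self.joint_types.items()))
        lines.append("Skeleton pose fit")
        lines.append("=" * 64)
        lines.append(f"Joint model:        {types}")
        lines.append(f"Mean residual:      {self.mean_residual_mm:.4f} mm")
        lines.append(f"Max coincidence:    {self.max_coincidence_mm:.3e} mm")
        lines.append(f"Max axis dot:       {self.max_axis_dot:.3e}")
        lines.append(f"Status:             {self.status}")
        lines.append("")
        lines.append("Residual table (mm):")
        lines.append(self.residual_table.round(4).to_string())
        if self.joints is not None:
            lines.append("")
            lines.append("Joint estimates:")
            for jid, joint in sorted(self.joints.items()):
                c = joint.center
                s = f"  joint {jid} ({joint.bone_a}-{joint.bone_b}, {joint.joint_type}): " \
                    f"center ({c[0]:.2f}, {c[1]:.2f}, {c[2]:.2f}) mm"
                if joint.u_b3 is not None:
                    a = canonical_axis_sign(joint.u_b3)
                    s += f", axis ({a[0]:.4f}, {a[1]:.4f}, {a[2]:.4f})"
                lines.append(s)
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "joint_types": {str(k): v for k, v in self.joint_types.items()},
            "mean_residual_mm": self.mean_residual_mm,
            "residual_table_mm": {p: {b: float(v) for b, v in row.items()}
                                  for p, row in self.residual_table.iterrows()},
            "transforms": {p: {b: t.as_dict() for b, t in tf.items()}
                           for p, tf in self.transforms.items()},
            "joints": None if self.joints is None
                      else {str(j): s.as_dict() for j, s in self.joints.items()},
            "max_coincidence_mm": self.max_coincidence_mm,
            "max_axis_dot": self.max_axis_dot,
            "status": self.status,
        }

    def plot_residuals(self, ax=None):
        """Bar chart of the residual table (one group per posture)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.2))
        self.residual_table.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("residual (mm)")
        ax.set_title("Bone fitting residuals")
        return ax


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class SkeletonPoseModel:
    """Pose-fitting model for a multi-posture bone-cloud dataset.

    Parameters
    ----------
    reference:
        mapping bone id -> :class:`BoneCloud` in the reference
        (full-extension) posture.  The reference pose is the gauge: its
        transforms are the identity.
    postures:
        mapping posture name -> {bone id -> cloud} for every non-reference
        posture.
    topology:
        which bones each of the four joints connects.
    """

    def __init__(self, reference: dict[str, BoneCloud],
                 postures: dict[str, dict[str, BoneCloud]],
                 topology: JointTopology = DEFAULT_TOPOLOGY):
        if not postures:
            raise ValueError("need at least one non-reference posture")
        self.reference = dict(reference)
        self.postures = {p: dict(c) for p, c in postures.items()}
        self.topology = topology
        self.bones = [b for b in BONES if b in reference] or list(reference)
        for p, clouds in self.postures.items():
            missing = [b for b in self.bones if b not in clouds]
            if missing:
                raise ValueError(f"posture {p!r} lacks clouds for {missing}")
        self._cache: dict = {}

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataset(cls, dataset, use_noiseless: bool = False,
                     topology: JointTopology = DEFAULT_TOPOLOGY) -> "SkeletonPoseModel":
        """Build from a :class:`~wingkin.skeleton.PosedSkeletonDataset`."""
        clouds = dataset.noiseless if use_noiseless else dataset.clouds
        postures = {p: clouds[p] for p in dataset.non_reference_postures}
        return cls(dataset.reference, postures, topology=topology)

    # -- internal helpers ------------------------------------------------
    def _trees(self, downsample: int, seed: int):
        key = ("trees", downsample, seed)
        if key not in self._cache:
            trees = {}
            for b in self.bones:
                ds_ref = self.reference[b].subsample(downsample, seed=seed)
                trees[b] = cKDTree(ds_ref.points)
            ds_targets = {p: {b: self.postures[p][b].subsample(downsample, seed=seed + 1).points
                              for b in self.bones} for p in self.postures}
            self._cache[key] = (trees, ds_targets)
        return self._cache[key]

    def _chamfer(self, posture: str, bone: str, rot: np.ndarray, trans: np.ndarray,
                 downsample: int, seed: int) -> float:
        trees, targets = self._trees(downsample, seed)
        back = (targets[posture][bone] - trans) @ rot
        d, _ = trees[bone].query(back, k=1)
        return float(np.mean(d))

    def _full_residual_table(self, transforms) -> pd.DataFrame:
        from .registration import residual
        rows = {}
        for p in self.postures:
            rows[p] = {b: residual(self.postures[p][b],
                                   transforms[p][b].apply(self.reference[b].points))
                       for b in self.bones}
        table = pd.DataFrame.from_dict(rows, orient="index")[self.bones]
        table.index.name = "posture"
        return table

    def base_fits(self, options: FitOptions | None = None) -> dict[tuple[str, str], PoseFit]:
        """Unconstrained per-bone multi-start fits (cached per option set)."""
        opt = options or FitOptions()
        key = ("base", opt)
        if key not in self._cache:
            fits = {}
            for p in self.postures:
                for b in self.bones:
                    fits[(p, b)] = fit_pose_unconstrained(
                        self.reference[b], self.postures[p][b], opt)
            self._cache[key] = fits
        return self._cache[key]

    def _centerline_midpoint_init(self, joint_id: int, bone_a: str, bone_b: str) -> np.ndarray:
        ca = self.reference[bone_a].centerline
        cb = self.reference[bone_b].centerline
        if ca is None or cb is None:
            pa = self.reference[bone_a].points.mean(axis=0)
            pb = self.reference[bone_b].points.mean(axis=0)
            return 0.5 * (pa + pb)
        ends_a = [ca[0], ca[-1]]
        ends_b = [cb[0], cb[-1]]
        pairs = [(ea, eb) for ea in ends_a for eb in ends_b]
        ea, eb = min(pairs, key=lambda pr: np.linalg.norm(pr[0] - pr[1]))
        return 0.5 * (ea + eb)

    def _estimate_joints(self, joint_types: dict[int, str], transforms,
                         previous: dict[int, JointSpec] | None = None) -> dict[int, JointSpec]:
        """Closed-form joint parameters minimising Eq-5 violations for the
        current transforms."""
        joints = {}
        for jid, bone_a, bone_b in self.topology.pairs:
            jtype = joint_types[jid]
            init = (previous[jid].center if previous is not None
                    else self._centerline_midpoint_init(jid, bone_a, bone_b))
            pairs = [(transforms[p][bone_a], transforms[p][bone_b]) for p in self.postures]
            center = estimate_center(pairs, init)
            rels = [relative_rotation(ta, tb) for ta, tb in pairs]
            u_a1 = u_a2 = u_b3 = None
            if jtype == "revolute":
                u_b3 = estimate_revolute_axis(rels)
                u_a1, u_a2 = orthonormal_complement(u_b3)
            elif jtype == "universal":
                u_a1, u_b3 = estimate_universal_axes(rels)
            joints[jid] = JointSpec(jid, bone_a, bone_b, jtype, center,
                                    u_a1=u_a1, u_a2=u_a2, u_b3=u_b3)
        return joints

    @staticmethod
    def _violations(joints: dict[int, JointSpec], transforms):
        max_c, max_a = 0.0, 0.0
        for posture_tf in transforms.values():
            for joint in joints.values():
                ta, tb = posture_tf[joint.bone_a], posture_tf[joint.bone_b]
                if joint.joint_type != "unrestrained":
                    max_c = max(max_c, coincidence_violation(joint, ta, tb))
                if joint.joint_type in ("universal", "revolute"):
                    max_a = max(max_a, max(abs(v) for v in axis_violations(joint, ta, tb)))
        return max_c, max_a

    def _penalty_terms(self, joints, posture_tf, bone: str, length_scale: float) -> float:
        total = 0.0
        for joint in joints.values():
            if joint.joint_type == "unrestrained":
                continue
            if bone not in (joint.bone_a, joint.bone_b):
                continue
            ta, tb = posture_tf[joint.bone_a], posture_tf[joint.bone_b]
            total += coincidence_violation(joint, ta, tb) ** 2
            if joint.joint_type in ("universal", "revolute"):
                total += length_scale ** 2 * sum(v ** 2 for v in axis_violations(joint, ta, tb))
        return total

    # -- fitting ---------------------------------------------------------
    def fit(self, joint_types: str | dict[int, str] | None = None,
            options: ConstrainedFitOptions | None = None,
            start: "SkeletonFitResults | None" = None) -> SkeletonFitResults:
        """Fit the model.

        ``joint_types`` is a preset name (``unrestrained``, ``ball``,
        ``universal``, ``revolute``, ``onedof``), a mapping joint id ->
        type, or None for the unconstrained baseline.  ``start`` warm-starts
        the transforms from a previous (typically less constrained) fit.
        """
        opt = options or ConstrainedFitOptions()
        if joint_types is None:
            joint_types = "unrestrained"
        if isinstance(joint_types, str):
            try:
                joint_types = MODEL_PRESETS[joint_types]
            except KeyError:
                raise ValueError(f"unknown model preset {joint_types!r}") from None
        joint_types = {int(k): v for k, v in joint_types.items()}

        base = self.base_fits(opt.pose_options)
        if start is not None:
            transforms = {p: dict(start.transforms[p]) for p in self.postures}
        else:
            transforms = {p: {b: base[(p, b)].transform for b in self.bones}
                          for p in self.postures}

        if all(t == "unrestrained" for t in joint_types.values()):
            table = self._full_residual_table(transforms)
            return SkeletonFitResults(joint_types=joint_types, transforms=transforms,
                                      joints=None, residual_table=table,
                                      base_fits=base, max_coincidence_mm=float("nan"),
                                      max_axis_dot=float("nan"), status="converged",
                                      model=self)

        ds, seed = opt.pose_options.downsample, opt.pose_options.seed
        joints = self._estimate_joints(joint_types, transforms)
        max_c, max_a = self._violations(joints, transforms)

        status = "converged"
        if max_c > opt.coincidence_tol_mm or max_a > opt.axis_tol:
            transforms, joints = self._penalty_refine(joint_types, transforms, joints, opt)

        transforms, joints, feasible = self._feasibility_polish(
            joint_types, transforms, joints, opt)
        if not feasible:
            status = "infeasible"
        joints = self._canonicalise_centers(joints)

        max_c, max_a = self._violations(joints, transforms)
        table = self._full_residual_table(transforms)
        return SkeletonFitResults(joint_types=joint_types, transforms=transforms,
                                  joints=joints, residual_table=table, base_fits=base,
                                  max_coincidence_mm=max_c, max_axis_dot=max_a,
                                  status=status, model=self)

    def _canonicalise_centers(self, joints: dict[int, JointSpec]) -> dict[int, JointSpec]:
        """Pin the unidentifiable axial component of hinge centers.

        A revolute joint's center is equivalent anywhere along its axis (the
        axis constraints make the coincidence equation invariant to axial
        shifts), so the reported center is the axis point nearest the
        anatomical initialisation (adjacent centerline endpoints midpoint).
        """
        out = {}
        for jid, joint in joints.items():
            if joint.joint_type == "revolute" and joint.u_b3 is not None:
                anchor = self._centerline_midpoint_init(jid, joint.bone_a, joint.bone_b)
                shift = (anchor - joint.center) @ joint.u_b3
                out[jid] = replace(joint, center=joint.center + shift * joint.u_b3)
            else:
                out[jid] = joint
        return out

    def _penalty_refine(self, joint_types, transforms, joints, opt: ConstrainedFitOptions):
        ds, seed = opt.pose_options.downsample, opt.pose_options.seed
        n_cells = len(self.postures) * len(self.bones)
        mu = opt.penalty_mu0
        for _ in range(opt.penalty_rounds):
            for _ in range(opt.sweeps_per_round):
                for p in self.postures:
                    for b in self.bones:
                        t0 = transforms[p][b]
                        x0 = np.concatenate([t0.euler_zyx, t0.translation])

                        def objective(x, p=p, b=b):
                            rot = euler_zyx_to_matrix(x[:3])
                            cand = RigidTransform.from_matrix(rot, x[3:])
                            posture_tf = dict(transforms[p])
                            posture_tf[b] = cand
                            cham = self._chamfer(p, b, rot, x[3:], ds, seed) / n_cells
                            pen = self._penalty_terms(joints, posture_tf, b,
                                                      opt.length_scale_mm)
                            return cham + mu * pen

                        res = minimize(objective, x0, method="Nelder-Mead",
                                       options={"maxfev": opt.block_maxfev,
                                                "fatol": 1e-10, "xatol": 1e-8})
                        if res.fun < objective(x0):
                            transforms[p][b] = RigidTransform(res.x[:3], res.x[3:])
                joints = self._estimate_joints(joint_types, transforms, previous=joints)
            mu *= opt.penalty_factor
            max_c, max_a = self._violations(joints, transforms)
            if max_c < opt.coincidence_tol_mm and max_a < opt.axis_tol:
                break
        return transforms, joints

    def _feasibility_polish(self, joint_types, transforms, joints,
                            opt: ConstrainedFitOptions):
        """Project the solution onto the constraint manifold: Gauss-Newton on
        the violation residuals over all transforms and joint parameters."""
        postures = list(self.postures)
        x_parts, layout = [], []
        for p in postures:
            for b in self.bones:
                t = transforms[p][b]
                x_parts.append(np.concatenate([np.radians(t.euler_zyx), t.translation / 10.0]))
                layout.append(("tf", p, b))
        axis_layout = {}
        for jid, joint in joints.items():
            if joint.joint_type == "unrestrained":
                continue
            x_parts.append(joint.center / 10.0)
            layout.append(("center", jid))
            ap = _joint_axis_params(joint)
            if ap is not None:
                x_parts.append(ap)
                layout.append(("axis", jid))
                axis_layout[jid] = len(ap)
        if len(layout) == len(postures) * len(self.bones):  # no active constraints
            return transforms, joints, True
        x0 = np.concatenate(x_parts)

        def unpack(x):
            tfs = {p: {} for p in postures}
            centers, axes = {}, {}
            i = 0
            for item in layout:
                if item[0] == "tf":
                    _, p, b = item
                    seg = x[i:i + 6]; i += 6
                    tfs[p][b] = RigidTransform(np.degrees(seg[:3]), seg[3:] * 10.0)
                elif item[0] == "center":
                    _, jid = item
                    centers[jid] = x[i:i + 3] * 10.0; i += 3
                else:
                    _, jid = item
                    n = axis_layout[jid]
                    axes[jid] = x[i:i + n]; i += n
            js = {jid: _joint_from_params(j, centers.get(jid, j.center), axes.get(jid))
                  for jid, j in joints.items()}
            return tfs, js

        def resid(x):
            tfs, js = unpack(x)
            out = []
            for p in postures:
                for joint in js.values():
                    if joint.joint_type == "unrestrained":
                        continue
                    ta, tb = tfs[p][joint.bone_a], tfs[p][joint.bone_b]
                    out.extend(ta.apply(joint.center) - tb.apply(joint.center))
                    if joint.joint_type in ("universal", "revolute"):
                        out.extend(opt.length_scale_mm * v
                                   for v in axis_violations(joint, ta, tb))
            return np.asarray(out)

        sol = least_squares(resid, x0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=400 * max(1, len(x0) // 10))
        tfs, js = unpack(sol.x)
        max_c, max_a = self._violations(js, tfs)
        feasible = max_c <= opt.coincidence_tol_mm and max_a <= opt.axis_tol
        if not feasible and np.linalg.norm(sol.fun) >= np.linalg.norm(resid(x0)):
            return transforms, joints, False
        return tfs, js, feasible

    # -- model comparison ------------------------------------------------
    def compare(self, models=("unrestrained", "ball", "universal", "revolute"),
                options: ConstrainedFitOptions | None = None) -> "ModelComparison":
        """Fit several joint models and tabulate their mean residuals against
        the unconstrained baseline."""
        return compare_joint_models(self, models, options)


def fit_skeleton_constrained(reference, postures, joint_types="onedof",
                             topology: JointTopology = DEFAULT_TOPOLOGY,
                             options: ConstrainedFitOptions | None = None) -> SkeletonFitResults:
    """Functional wrapper: build a :class:`SkeletonPoseModel` and fit it."""
    return SkeletonPoseModel(reference, postures, topology).fit(joint_types, options)


@dataclass
class ModelComparison:
    """Mean residuals and relative deviations of several joint models."""

    results: dict[str, SkeletonFitResults]
    baseline: str = "unrestrained"

    @property
    def table(self) -> pd.DataFrame:
        base = self.results[self.baseline].mean_residual_mm
        rows = []
        for name, res in self.results.items():
            rows.append({
                "model": name,
                "mean_mm": res.mean_residual_mm,
                "relative_deviation_pct": 100.0 * (res.mean_residual_mm - base) / base,
                "max_coincidence_mm": res.max_coincidence_mm,
                "status": res.status,
            })
        return pd.DataFrame(rows).set_index("model")

    def summary(self) -> str:
        lines = ["Joint-model comparison", "=" * 64,
                 self.table.round(4).to_string(), "",
                 f"(relative deviation is vs the {self.baseline!r} baseline)"]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {name: {**res.as_dict(),
                       "relative_deviation_pct":
                           float(self.table.loc[name, "relative_deviation_pct"])}
                for name, res in self.results.items()}


def compare_joint_models(model: SkeletonPoseModel,
                         models=("unrestrained", "ball", "universal", "revolute"),
                         options: ConstrainedFitOptions | None = None) -> ModelComparison:
    """Fit each requested joint model and compare mean residuals.

    Fits cascade: each model warm-starts from the best already-fitted model
    whose constraint set it contains.  Afterwards a consistency pass
    exploits the nesting of the constraint sets: a tighter model's solution
    is feasible for any looser model, so if it achieves a lower mean
    residual the looser model adopts it.  This makes the reported means
    non-decreasing with constraint strictness by construction.
    """
    names = list(models)
    if "unrestrained" not in names:
        names.insert(0, "unrestrained")
    typed = {n: MODEL_PRESETS[n] if isinstance(n, str) else n for n in names}

    results: dict[str, SkeletonFitResults] = {}
    for name in names:
        start = None
        candidates = [n for n in results if _nested(typed[n], typed[name])]
        if candidates:
            start = results[min(candidates, key=lambda n: results[n].mean_residual_mm)]
        results[name] = model.fit(typed[name], options, start=start)

    # nesting consistency pass: looser models may adopt tighter solutions
    for loose in names:
        for tight in names:
            if loose == tight or not _nested(typed[loose], typed[tight]):
                continue
            if results[tight].mean_residual_mm < results[loose].mean_residual_mm:
                adopted = results[tight]
                results[loose] = SkeletonFitResults(
                    joint_types=typed[loose],
                    transforms=adopted.transforms,
                    joints=adopted.joints if any(
                        t != "unrestrained" for t in typed[loose].values()) else None,
                    residual_table=adopted.residual_table,
                    base_fits=adopted.base_fits,
                    max_coincidence_mm=adopted.max_coincidence_mm,
                    max_axis_dot=adopted.max_axis_dot,
                    status=adopted.status, model=model)
    return ModelComparison(results=results)
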