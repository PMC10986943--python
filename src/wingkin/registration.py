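"""Unconstrained rigid registration of bone clouds.

The fitting criterion is the one-sided mean nearest-neighbour distance

    resid(target, candidate) = (1/n1) * sum_i min_j || X_i - Xnew_j ||

where ``X_i`` are the points of the posture cloud being matched (the target)
and ``Xnew_j`` the points of the transformed full-extension cloud (the
candidate).  The pose estimate minimises this residual over the six rigid
parameters by multi-start local search: each start runs an exact-1NN ICP
inner loop (closed-form Kabsch updates) and the best start is polished with
Nelder-Mead on the exact residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cloud import BoneCloud
from .geometry import RigidTransform, euler_zyx_to_matrix

__all__ = ["residual", "mean_residual", "FitOptions", "PoseFit", "fit_pose_unconstrained"]


def _points(cloud) -> np.ndarray:
    pts = cloud.points if isinstance(cloud, BoneCloud) else np.asarray(cloud, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise ValueError("expected a non-empty (N, 3) point set")
    return pts


def residual(target, candidate) -> float:
    """One-sided mean nearest-neighbour distance (mm) from ``target`` to ``candidate``."""
    tgt = _points(target)
    cand = _points(candidate)
    d, _ = cKDTree(cand).query(tgt, k=1)
    return float(np.mean(d))


def mean_residual(table: pd.DataFrame | np.ndarray) -> float:
    """Arithmetic mean of a complete residual table (bones x postures, mm).

    Accepts a DataFrame or array; every entry must be present and finite.
    """
    values = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) else np.asarray(table, float)
    if values.size == 0:
        raise ValueError("empty residual table")
    if not np.all(np.isfinite(values)):
        raise ValueError("residual table has missing or non-finite entries")
    return float(values.mean())


@dataclass(frozen=True)
class FitOptions:
    """Options for the multi-start pose search.

    ``n_starts`` local searches are run: the identity-rotation centroid
    alignment plus seeded random rotations of at most ``max_start_rot_deg``.
    Clouds larger than ``downsample`` points are uniformly subsampled
    (seeded) for the search; the reported residual is recomputed on the full
    clouds.  Ties between starts break to the lower residual, then the lower
    start index.
    """

    n_starts: int = 8
    seed: int = 0
    downsample: int = 2000
    max_start_rot_deg: float = 60.0
    icp_max_iter: int = 80
    icp_tol: float = 1e-12
    nm_maxfev: int = 2000
    nm_fatol: float = 1e-6
    polish: bool = True

    def __post_init__(self):
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")


@dataclass(frozen=True)
class PoseFit:
    """Result of an unconstrained pose fit."""

    transform: RigidTransform
    residual_mm: float
    status: str
    start_index: int
    start_residuals: np.ndarray

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    def as_dict(self) -> dict:
        d = self.transform.as_dict()
        d.update(residual_mm=float(self.residual_mm), status=self.status)
        return d


def _chamfer_via_ref_tree(ref_tree: cKDTree, target_pts: np.ndarray, rot: np.ndarray,
                          trans: np.ndarray) -> float:
    # min_j |X_i - (R x_j + t)| == min_j |R^T (X_i - t) - x_j|: query a fixed
    # tree on the reference cloud with inversely transformed target points.
    back = (target_pts - trans) @ rot
    d, _ = ref_tree.query(back, k=1)
    return float(np.mean(d))


def _kabsch(src: np.ndarray, dst: np.ndarray):
    """Rotation/translation minimising sum |dst - (R src + t)|^2."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - cd, src - cs)
    mat = rot.as_matrix()
    return mat, cd - mat @ cs


def _icp(ref_pts: np.ndarray, ref_tree: cKDTree, tgt_pts: np.ndarray,
         rot0: np.ndarray, trans0: np.ndarray, max_iter: int, tol: float):
    rot, trans = rot0, trans0
    prev = np.inf
    for _ in range(max_iter):
        back = (tgt_pts - trans) @ rot
        d, idx = ref_tree.query(back, k=1)
        obj = float(np.mean(d**2))
        if prev - obj < tol * max(1.0, prev):
            break
        prev = obj
        rot, trans = _kabsch(ref_pts[idx], tgt_pts)
    return rot, trans


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0.0, max_deg))
    return Rotation.from_rotvec(ang * axis).as_matrix()


def fit_pose_unconstrained(reference: BoneCloud, target: BoneCloud,
                           options: FitOptions | None = None) -> PoseFit:
    """Estimate the rigid transform carrying ``reference`` onto ``target``.

    Returns the transform minimising ``residual(target, transform(reference))``
    over the multi-start search, together with the residual recomputed at the
    returned transform on the full clouds (self-consistent by construction).
    """
    opt = options or FitOptions()
    ref_full = _points(reference)
    tgt_full = _points(target)

    ref_ds = BoneCloud(ref_full).subsample(opt.downsample, seed=opt.seed).points
    tgt_ds = BoneCloud(tgt_full).subsample(opt.downsample, seed=opt.seed + 1).points
    ref_tree = cKDTree(ref_ds)

    rng = np.random.default_rng(opt.seed)
    c_ref, c_tgt = ref_ds.mean(axis=0), tgt_ds.mean(axis=0)

    best = None
    start_residuals = np.empty(opt.n_starts)
    for s in range(opt.n_starts):
        rot0 = np.eye(3) if s == 0 else _random_rotation(rng, opt.max_start_rot_deg)
        trans0 = c_tgt - rot0 @ c_ref
        rot, trans = _icp(ref_ds, ref_tree, tgt_ds, rot0, trans0,
                          opt.icp_max_iter, opt.icp_tol)
        r = _chamfer_via_ref_tree(ref_tree, tgt_ds, rot, trans)
        start_residuals[s] = r
        if best is None or r < best[0] - 1e-15:
            best = (r, s, rot, trans)

    r_best, s_best, rot, trans = best

    status = "converged"
    if opt.polish:
        x0 = np.concatenate([RigidTransform.from_matrix(rot, trans).euler_zyx, trans])

        def objective(x):
            return _chamfer_via_ref_tree(ref_tree, tgt_ds, euler_zyx_to_matrix(x[:3]), x[3:])

        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"maxfev": opt.nm_maxfev, "fatol": opt.nm_fatol,
                                "xatol": 1e-8})
        if res.fun <= r_best:
            rot, trans = euler_zyx_to_matrix(res.x[:3]), res.x[3:]
        if not res.success and res.fun > r_best:
            status = "max_evaluations"

    transform = RigidTransform.from_matrix(rot, trans)
    final = residual(tgt_full, transform.apply(ref_full))
    return PoseFit(transform=transform, residual_mm=final, status=status,
                   start_index=int(s_best), start_residuals=start_residuals)
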