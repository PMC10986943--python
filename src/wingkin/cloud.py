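"""Bone point-cloud container."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import RigidTransform

__all__ = ["BoneCloud", "apply_transform", "BONES", "POSTURES"]

#: canonical bone chain, proximal to distal (the radius runs beside the ulna)
BONES = ("humerus", "ulna", "radius", "metacarpal")

#: the three scanned wing postures, reference first
POSTURES = ("extension", "half_extension", "flexion")


@dataclass(frozen=True)
class BoneCloud:
    """Point cloud of one bone in one posture.

    Parameters
    ----------
    points:
        (N, 3) surface points, mm. N >= 3, finite.
    centerline:
        optional (M, 3) ordered polyline along the bone, mm.
    bone_id, posture_id:
        labels; ``bone_id`` is typically one of :data:`BONES`.
    """

    points: np.ndarray
    centerline: np.ndarray | None = None
    bone_id: str = ""
    posture_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if pts.shape[0] < 3:
            raise ValueError("a bone cloud needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite coordinates in point cloud")
        object.__setattr__(self, "points", pts)
        if self.centerline is not None:
            cl = np.asarray(self.centerline, float)
            if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
                raise ValueError("centerline must be an (M>=2, 3) polyline")
            object.__setattr__(self, "centerline", cl)

    def __len__(self) -> int:
        return self.points.shape[0]

    def transformed(self, t: RigidTransform) -> "BoneCloud":
        cl = None if self.centerline is None else t.apply(self.centerline)
        return replace(self, points=t.apply(self.points), centerline=cl)

    def subsample(self, n: int, seed: int = 0) -> "BoneCloud":
        """Seeded uniform subsample without replacement (no-op if N <= n)."""
        if len(self) <= n:
            return self
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self), size=n, replace=False)
        idx.sort()
        return replace(self, points=self.points[idx])


def apply_transform(cloud: BoneCloud, t: RigidTransform) -> BoneCloud:
    """Map every point (and the centerline) through ``x -> A x + t``."""
    return cloud.transformed(t)
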