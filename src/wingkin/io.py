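"""Reading and writing the pipeline's file formats.

Point clouds: PLY (ASCII or binary, via trimesh), XYZ (whitespace floats)
and CSV with the header ``x_mm,y_mm,z_mm``.  Fits, ground truth and run
manifests are JSON; sensor streams and sweep tables are CSV.  All lengths
are mm, angles degrees, forces N — units are carried in column names or
metadata fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cloud import BoneCloud
from .geometry import RigidTransform

__all__ = [
    "read_cloud",
    "write_cloud",
    "write_truth_json",
    "read_truth_json",
    "write_fits_json",
    "read_streams_csv",
    "write_streams_csv",
]

_CSV_HEADER = ["x_mm", "y_mm", "z_mm"]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "xyz", "csv"):
        return suffix
    raise ValueError(f"cannot infer cloud format from {path.name!r}; pass format=")


def read_cloud(path, format: str | None = None, bone_id: str = "",
               posture_id: str = "") -> BoneCloud:
    """Read a point cloud (mm) from PLY, XYZ or CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        import trimesh
        obj = trimesh.load(str(path), process=False)
        pts = np.asarray(obj.vertices, float)
        if pts.size == 0:
            raise ValueError(f"{path}: empty PLY cloud")
    elif fmt == "xyz":
        try:
            pts = np.loadtxt(str(path), ndmin=2)
        except ValueError as err:
            raise ValueError(f"{path}: malformed XYZ file ({err})") from err
        if pts.size == 0:
            raise ValueError(f"{path}: empty XYZ cloud")
        if pts.shape[1] != 3:
            raise ValueError(f"{path}: expected 3 columns, found {pts.shape[1]}")
    elif fmt == "csv":
        df = pd.read_csv(path)
        if list(df.columns[:3]) != _CSV_HEADER:
            raise ValueError(
                f"{path}: unknown CSV header {list(df.columns[:3])!r}; "
                f"expected {_CSV_HEADER}")
        pts = df[_CSV_HEADER].to_numpy(float)
    else:
        raise ValueError(f"unsupported cloud format {fmt!r}")
    return BoneCloud(points=pts, bone_id=bone_id or path.stem, posture_id=posture_id)


def write_cloud(cloud: BoneCloud, path, format: str | None = None,
                encoding: str = "binary") -> Path:
    """Write a point cloud; PLY supports ``encoding`` 'binary' or 'ascii'."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        path.write_bytes(_export_ply_double(cloud.points, encoding))
    elif fmt == "xyz":
        np.savetxt(str(path), cloud.points, fmt="%.9g")
    elif fmt == "csv":
        pd.DataFrame(cloud.points, columns=_CSV_HEADER).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported cloud format {fmt!r}")
    return path


def _export_ply_double(points: np.ndarray, encoding: str) -> bytes:
    # double-precision vertex PLY (readers take the dtype from the header)
    if encoding not in ("ascii", "binary"):
        raise ValueError(f"unsupported PLY encoding {encoding!r}")
    fmt = "ascii" if encoding == "ascii" else "binary_little_endian"
    header = "\n".join([
        "ply",
        f"format {fmt} 1.0",
        f"element vertex {len(points)}",
        "property double x",
        "property double y",
        "property double z",
        "end_header",
    ]) + "\n"
    if encoding == "ascii":
        body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in points) + "\n"
        return (header + body).encode()
    return header.encode() + np.ascontiguousarray(points, dtype="<f8").tobytes()


def write_truth_json(dataset, path) -> Path:
    """Ground truth of a posed synthetic dataset: per-posture Euler angles
    (deg) and translations (mm) per bone, joint centers/axes (global
    reference frame), drive angles and noise level."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "units": {"length": "mm", "angle": "deg"},
        "seed": dataset.seed,
        "noise_sd_mm": dataset.noise_sd,
        "angles_deg": {p: list(a) for p, a in dataset.angles.items()},
        "transforms": {p: {b: t.as_dict() for b, t in tf.items()}
                       for p, tf in dataset.transforms.items()},
        "joints": {str(j): s.as_dict() for j, s in dataset.truth.joints.items()},
        "landmarks_mm": {k: [float(x) for x in v]
                         for k, v in dataset.truth.landmarks.items()},
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_truth_json(path) -> dict:
    data = json.loads(Path(path).read_text())
    data["transforms"] = {p: {b: RigidTransform.from_dict(d) for b, d in tf.items()}
                          for p, tf in data["transforms"].items()}
    return data


def write_fits_json(fits: dict, path) -> Path:
    """Write per-bone pose fits: {posture: {bone: {euler_deg, translation_mm,
    residual_mm, status}}}."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {p: {b: f.as_dict() for b, f in by_bone.items()}
               for p, by_bone in fits.items()}
    path.write_text(json.dumps({"units": {"length": "mm", "angle": "deg"},
                                "fits": payload}, indent=1))
    return path


_STREAM_COLS = ["time_s", "sensor_id", "qw", "qx", "qy", "qz"]


def read_streams_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _STREAM_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sensor stream CSV lacks columns {missing}")
    return df[_STREAM_COLS]


def write_streams_csv(streams: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    streams[_STREAM_COLS].to_csv(path, index=False)
    return path
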