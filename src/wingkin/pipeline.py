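"""End-to-end pipeline: simulate -> fit -> compare -> reproduce -> sweep -> sensors.

The pipeline mirrors the study's workflow on the synthetic skeleton: pose
the articulated skeleton into the scanned postures, fit every bone's pose
without constraints, re-fit under the candidate joint models and compare
their residuals, reproduce the postures with the 1-DOF mechanism, sweep the
cable endpoint candidates, and finally synthesise and process sensor
quaternion streams.  All outputs are plain text (XYZ/PLY/CSV/JSON) under
one output directory, with a manifest recording seeds and per-stage status;
a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .actuation import default_actuation_config, sweep_endpoints
from .io import write_cloud, write_fits_json, write_streams_csv, write_truth_json
from .mechanism import reproduce_postures
from .model import ConstrainedFitOptions, SkeletonPoseModel
from .registration import FitOptions
from .sensors import joint_angle_series, synthesize_streams
from .skeleton import default_skeleton, pose_skeleton

__all__ = ["RunConfig", "run_pipeline", "load_config"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (units: mm, degrees, N)."""

    seed: int = 0
    out_dir: str = "wingkin_run"
    n_points: int = 2000
    noise_sd_mm: float = 0.3
    downsample: int = 2000
    n_starts: int = 8
    models: tuple[str, ...] = ("unrestrained", "ball", "universal", "revolute", "onedof")
    sweep_samples: int = 101
    sensor_samples: int = 101
    sensor_duration_s: float = 5.0
    write_ply: bool = True
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        self.models = tuple(self.models)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration (versioned schema)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    version = raw.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def run_pipeline(config: RunConfig, log=print) -> dict:
    """Execute all stages; returns the manifest dictionary.

    Any stage failure raises after the manifest (with the completed stages)
    is written, so partial outputs are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "wingkin",
        "version": __version__,
        "schema_version": config.schema_version,
        "seed": config.seed,
        "config": {**asdict(config), "models": list(config.models)},
        "units": {"length": "mm", "angle": "deg", "force": "N"},
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            log(f"[wingkin] stage {name} ...")
            try:
                fn()
            except Exception as err:
                manifest["stages"][name] = {"status": f"failed: {err}"}
                (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.perf_counter() - t0, 2)}
        return wrap

    holder = {}

    @stage("simulate")
    def _simulate():
        truth = default_skeleton(seed=config.seed, n_points=config.n_points)
        dataset = pose_skeleton(truth, noise_sd=config.noise_sd_mm, seed=config.seed + 1)
        holder["truth"], holder["dataset"] = truth, dataset
        for posture, by_bone in dataset.clouds.items():
            for bone, cloud in by_bone.items():
                write_cloud(cloud, out / "clouds" / posture / f"{bone}.xyz")
                if config.write_ply:
                    write_cloud(cloud, out / "clouds" / posture / f"{bone}.ply",
                                encoding="ascii")
        for bone, cloud in dataset.reference.items():
            write_cloud(cloud, out / "clouds" / "extension" / f"{bone}.xyz")
            if config.write_ply:
                write_cloud(cloud, out / "clouds" / "extension" / f"{bone}.ply",
                            encoding="ascii")
        write_truth_json(dataset, out / "truth.json")

    @stage("fit_unconstrained")
    def _fit_unconstrained():
        dataset = holder["dataset"]
        model = SkeletonPoseModel.from_dataset(dataset)
        holder["model"] = model
        opts = FitOptions(seed=config.seed + 2, downsample=config.downsample,
                          n_starts=config.n_starts)
        holder["fit_options"] = ConstrainedFitOptions(pose_options=opts)
        base = model.base_fits(opts)
        fits = {}
        for (posture, bone), fit in base.items():
            fits.setdefault(posture, {})[bone] = fit
        write_fits_json(fits, out / "fits_unconstrained.json")

    @stage("compare_models")
    def _compare():
        model = holder["model"]
        cmp = model.compare(config.models, options=holder["fit_options"])
        holder["comparison"] = cmp
        cmp.table.to_csv(out / "model_comparison.csv")
        (out / "model_comparison.json").write_text(json.dumps(cmp.as_dict(), indent=1))
        for name, res in cmp.results.items():
            res.residual_table.to_csv(out / f"residual_table_{name}.csv")

    @stage("reproduce_onedof")
    def _reproduce():
        dataset = holder["dataset"]
        table, thetas = reproduce_postures(
            dataset.truth.config, dataset.reference,
            {p: dataset.clouds[p] for p in dataset.non_reference_postures},
            downsample=config.downsample, seed=config.seed + 3)
        table.to_csv(out / "onedof_reproduction.csv")
        (out / "onedof_theta1.json").write_text(json.dumps(
            {"theta1_deg": thetas, "mean_residual_mm": float(table.to_numpy().mean())},
            indent=1))

    @stage("sweep_actuation")
    def _sweep():
        cfg = holder["truth"].config
        act = default_actuation_config(cfg)
        table, selected = sweep_endpoints(cfg, act, n_samples=config.sweep_samples)
        table.to_csv(out / "sweep.csv")
        (out / "sweep_selection.json").write_text(json.dumps(
            {"selected": selected,
             **{k: float(v) for k, v in table.loc[selected].items()
                if isinstance(v, (float, np.floating))}}, indent=1))

    @stage("sensors")
    def _sensors():
        cfg = holder["truth"].config
        theta1 = np.linspace(0.0, cfg.theta1_max, config.sensor_samples)
        t = np.linspace(0.0, config.sensor_duration_s, config.sensor_samples)
        streams = synthesize_streams(cfg, theta1, 0.0, t)
        write_streams_csv(streams, out / "sensor_streams.csv")
        extrema = {}
        for series in joint_angle_series(streams):
            series.to_frame().to_csv(out / f"joint{series.joint_id}_angles.csv",
                                     index=False)
            extrema[f"joint{series.joint_id}"] = series.extrema()
        (out / "sensor_extrema.json").write_text(json.dumps(extrema, indent=1))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log(f"[wingkin] run complete -> {out}")
    return manifest
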