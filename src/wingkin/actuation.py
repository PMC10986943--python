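"""Quasi-static cable-spring actuation of the bionic wing skeleton.

Two antagonistic ropes drive the extension/flexion stroke: rope 1 (the
biceps analogue) runs from a linear motor anchored on the humerus (site BH)
to the proximal ulna (site BU); rope 2 (the triceps analogue) runs from the
ulnar olecranon (site TU) across the elbow to a spring anchored on the
humerus (site TH).  Ropes are straight segments between their endpoints
(no wrapping), the spring is linear with a preload, and inertia and
friction are neglected, so the motor force follows from virtual work:

    F_motor(theta1) = F_spring(theta1) * |dL2/dtheta1| / |dL1/dtheta1|

with rope-length derivatives taken by central differences in the drive
angle.  Each of the four attachment sites has three candidate endpoints,
giving the 3^4 = 81 cases of the endpoint sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .mechanism import MechanismConfig, MechanismState, mechanism_forward

__all__ = [
    "RopePoint",
    "ActuationConfig",
    "default_actuation_config",
    "rope_length",
    "spring_force",
    "motor_force",
    "sweep_endpoints",
]


@dataclass(frozen=True)
class RopePoint:
    """A rope endpoint fixed to a bone (reference-frame coordinates, mm).

    ``bone_id`` may be ``"base"`` for points fixed to the ground bracket.
    """

    bone_id: str
    point: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, float).reshape(3))

    def position(self, state: MechanismState) -> np.ndarray:
        if self.bone_id == "base":
            return self.point
        try:
            t = state.transforms[self.bone_id]
        except KeyError:
            raise ValueError(f"unknown bone id {self.bone_id!r} for rope endpoint") from None
        return t.apply(self.point)


@dataclass(frozen=True)
class ActuationConfig:
    """Spring/motor parameters and the candidate rope endpoints.

    ``candidates`` maps site name (BU, BH, TU, TH) to exactly three
    :class:`RopePoint` candidates; spacings follow the bionic design
    (10 mm on BU, 30 mm on BH, 3 mm on TU, 5 mm on TH).
    """

    candidates: dict[str, tuple[RopePoint, RopePoint, RopePoint]]
    spring_stiffness_n_mm: float = 0.187
    spring_preload_n: float = 4.5
    motor_speed_mm_s: float = 8.0
    motor_force_bounds_n: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self):
        if self.spring_stiffness_n_mm <= 0:
            raise ValueError("spring stiffness must be positive")
        if self.spring_preload_n < 0:
            raise ValueError("spring preload must be non-negative")
        for site in ("BU", "BH", "TU", "TH"):
            if site not in self.candidates or len(self.candidates[site]) != 3:
                raise ValueError(f"site {site} needs exactly 3 candidate endpoints")


def default_actuation_config(config: MechanismConfig) -> ActuationConfig:
    """Candidate endpoints on the default wing geometry.

    BU candidates sit on the cranial proximal ulna (10 mm apart, BU1 most
    proximal), BH on the cranial humerus (30 mm apart), TU on the ulnar
    olecranon — prolonged proximally past the elbow on the caudal side
    (3 mm apart) — and TH on the caudal humerus (5 mm apart).
    """
    geom = config.geometry
    u_dir = _unit(geom.wrist - geom.elbow)        # along the ulna, distal
    h_dir = _unit(geom.elbow - geom.shoulder)     # along the humerus, distal
    z = np.array([0.0, 0.0, 1.0])
    cranial_u = _unit(np.cross(z, u_dir))         # +Y-ish side of the ulna
    cranial_h = _unit(np.cross(z, h_dir))
    caudal_u, caudal_h = -cranial_u, -cranial_h

    bu = tuple(RopePoint("ulna", geom.elbow + d * u_dir + 4.0 * cranial_u)
               for d in (8.0, 18.0, 28.0))
    bh = tuple(RopePoint("humerus", geom.shoulder + d * h_dir + 4.0 * cranial_h)
               for d in (2.0, 32.0, 62.0))
    tu = tuple(RopePoint("ulna", geom.elbow - d * u_dir + 4.0 * caudal_u)
               for d in (5.0, 8.0, 11.0))
    th = tuple(RopePoint("humerus", geom.shoulder + d * h_dir + 4.0 * caudal_h)
               for d in (10.0, 15.0, 20.0))
    return ActuationConfig(candidates={"BU": bu, "BH": bh, "TU": tu, "TH": th})


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def rope_length(state: MechanismState, path) -> float:
    """Length (mm) of a straight-segment rope through ``path`` (a sequence of
    :class:`RopePoint`), each endpoint carried by its owning bone."""
    if len(path) < 2:
        raise ValueError("a rope path needs at least 2 points")
    pos = np.array([p.position(state) for p in path])
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


def spring_force(stretch_mm: float, cfg: ActuationConfig) -> float:
    """Linear spring law with preload: ``F = F0 + k * stretch`` (N).

    Negative stretch (a slack cable) is rejected: slack is outside the
    quasi-static model.
    """
    if stretch_mm < 0:
        raise ValueError("negative spring stretch: cable would be slack")
    return cfg.spring_preload_n + cfg.spring_stiffness_n_mm * stretch_mm


def motor_force(config: MechanismConfig, state: MechanismState,
                rope1_path, rope2_path, cfg: ActuationConfig,
                l2_reference: float | None = None,
                dtheta_deg: float = 0.01) -> float:
    """Quasi-static motor force (N) at the given mechanism state.

    The spring stretch is the rope-2 length relative to full extension
    (``l2_reference``, computed at theta1 = 0 if not supplied); derivatives
    of both rope lengths with respect to the drive angle use central
    differences of step ``dtheta_deg``.
    """
    th = state.theta1
    lo = max(0.0, th - dtheta_deg)
    hi = min(config.theta1_max, th + dtheta_deg)
    s_lo = mechanism_forward(config, lo, warm_state=state)
    s_hi = mechanism_forward(config, hi, warm_state=state)
    dl1 = (rope_length(s_hi, rope1_path) - rope_length(s_lo, rope1_path)) / (hi - lo)
    dl2 = (rope_length(s_hi, rope2_path) - rope_length(s_lo, rope2_path)) / (hi - lo)
    if abs(dl1) < 1e-9:
        raise ArithmeticError(
            f"singular configuration at theta1={th:g} deg: motor rope has no leverage")
    if l2_reference is None:
        l2_reference = rope_length(mechanism_forward(config, 0.0), rope2_path)
    stretch = rope_length(state, rope2_path) - l2_reference
    return spring_force(max(stretch, 0.0), cfg) * abs(dl2) / abs(dl1)


def _site_positions(states, candidates):
    """(3, T, 3) positions of each candidate of one site across the states."""
    return np.array([[rp.position(s) for s in states] for rp in candidates])


def sweep_endpoints(config: MechanismConfig, cfg: ActuationConfig,
                    n_samples: int = 101, dtheta_deg: float = 0.01) -> tuple[pd.DataFrame, str]:
    """Simulate the stroke for all 81 endpoint combinations.

    For each combination the drive angle sweeps 0 .. full contraction in
    ``n_samples`` uniform steps; the maxima of motor stretch, spring
    stretch, spring force and motor force are recorded.  A combination is
    feasible when its maximum motor force lies within the configured bound
    and the spring never goes slack; the selected combination has the
    smallest maximum motor force among feasible rows, ties broken by the
    smallest maximum spring stretch.

    Returns ``(table, selected_combo_id)``.
    """
    thetas = np.linspace(0.0, config.theta1_max, n_samples)

    def solve_grid(grid):
        states, warm = [], None
        for th in grid:
            warm = mechanism_forward(config, float(th), warm_state=warm)
            states.append(warm)
        return states

    states = solve_grid(thetas)
    states_lo = solve_grid(np.maximum(thetas - dtheta_deg, 0.0))
    states_hi = solve_grid(np.minimum(thetas + dtheta_deg, config.theta1_max))
    dth = (np.minimum(thetas + dtheta_deg, config.theta1_max)
           - np.maximum(thetas - dtheta_deg, 0.0))

    pos = {site: {grid: _site_positions(st, cfg.candidates[site])
                  for grid, st in (("mid", states), ("lo", states_lo), ("hi", states_hi))}
           for site in ("BU", "BH", "TU", "TH")}

    def lengths(site_a, i, site_b, j, grid):
        return np.linalg.norm(pos[site_a][grid][i] - pos[site_b][grid][j], axis=1)

    rows = []
    for i, j, k, l in product(range(3), repeat=4):
        combo = f"BU{i + 1}-BH{j + 1}-TU{k + 1}-TH{l + 1}"
        l1 = lengths("BH", j, "BU", i, "mid")
        l2 = lengths("TU", k, "TH", l, "mid")
        dl1 = (lengths("BH", j, "BU", i, "hi") - lengths("BH", j, "BU", i, "lo")) / dth
        dl2 = (lengths("TU", k, "TH", l, "hi") - lengths("TU", k, "TH", l, "lo")) / dth

        motor_stretch = np.abs(l1 - l1[0])
        s2 = l2 - l2[0]
        slack = bool(s2.min() < -1e-9)
        singular = bool(np.any(np.abs(dl1) < 1e-9))
        f_spring = cfg.spring_preload_n + cfg.spring_stiffness_n_mm * np.clip(s2, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_motor = np.where(np.abs(dl1) >= 1e-9,
                               f_spring * np.abs(dl2) / np.abs(dl1), np.nan)
        max_motor_force = float(np.nanmax(f_motor))
        lo_b, hi_b = cfg.motor_force_bounds_n
        feasible = (not slack and not singular
                    and lo_b <= max_motor_force <= hi_b)
        rows.append({
            "combo": combo,
            "max_motor_stretch_mm": float(motor_stretch.max()),
            "max_spring_stretch_mm": float(s2.max()),
            "max_spring_force_N": float(f_spring.max()),
            "max_motor_force_N": max_motor_force,
            "feasible": feasible,
            "slack": slack,
            "singular": singular,
        })

    table = pd.DataFrame(rows).set_index("combo")
    feas = table[table["feasible"]]
    pool = feas if len(feas) else table
    selected = pool.sort_values(
        ["max_motor_force_N", "max_spring_stretch_mm"]).index[0]
    return table, str(selected)
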