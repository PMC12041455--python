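"""Locomotor metrics from 2-D swim trajectories.

Total distance, mean velocity, clockwise/counter-clockwise rotation events,
mobility, and per-bin (2-min dark/light cycle) summaries — the quantities used
to characterise seizure-like swimming in larval zebrafish tracked at 30 fps.

Rotation semantics follow tracking-software convention: one rotation event is
a full 360 deg cumulative turn in one direction; a counter-turn larger than an
opposing tolerance (default 45 deg) resets the accumulator, and headings are
only updated once the larva has moved a minimum distance (default 1 mm) from
the last accepted point. The alternative reading — every 45 deg turn counts —
is available by setting ``full_turn_deg=45``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import Trajectory

__all__ = [
    "RotationSpec",
    "BehaviorReport",
    "total_distance",
    "mean_velocity",
    "count_rotations",
    "mobility",
    "bin_by_phase",
    "compute_report",
]


@dataclass(frozen=True)
class RotationSpec:
    full_turn_deg: float = 360.0
    opposing_tolerance_deg: float = 45.0
    min_step_mm: float = 1.0

    def __post_init__(self) -> None:
        if min(self.full_turn_deg, self.opposing_tolerance_deg, self.min_step_mm) <= 0:
            raise ValueError("all rotation parameters must be positive")
        if self.opposing_tolerance_deg >= self.full_turn_deg:
            raise ValueError("opposing tolerance must be below the full-turn angle")


def total_distance(traj: Trajectory) -> float:
    """Path length (mm): sum of successive Euclidean displacements."""
    if len(traj.times) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def mean_velocity(traj: Trajectory) -> float:
    """Average speed (mm/s) = total distance / elapsed time."""
    return total_distance(traj) / traj.duration_s


def _accepted_points(x: np.ndarray, y: np.ndarray, min_step: float) -> np.ndarray:
    """Indices of points at least ``min_step`` from the previously accepted one."""
    keep = [0]
    lx, ly = x[0], y[0]
    for i in range(1, x.size):
        if np.hypot(x[i] - lx, y[i] - ly) >= min_step:
            keep.append(i)
            lx, ly = x[i], y[i]
    return np.asarray(keep)


def count_rotations(traj: Trajectory,
                    spec: RotationSpec = RotationSpec()) -> tuple[int, int]:
    """(clockwise, counter-clockwise) rotation-event counts.

    Headings come from displacement vectors between accepted points (the
    ``min_step_mm`` filter suppresses tracking jitter); signed heading changes
    accumulate, a full turn counts one event and resets the accumulator, and a
    counter-turn beyond the opposing tolerance resets it without counting.
    Counter-clockwise is the positive mathematical direction.
    """
    if len(traj.times) < 3:
        raise ValueError("need at least 3 samples")
    idx = _accepted_points(traj.x, traj.y, spec.min_step_mm)
    if idx.size < 3:
        warnings.warn("fewer than 3 accepted points; no rotations counted")
        return 0, 0
    dx = np.diff(traj.x[idx])
    dy = np.diff(traj.y[idx])
    headings = np.degrees(np.arctan2(dy, dx))
    deltas = (np.diff(headings) + 180.0) % 360.0 - 180.0

    cw = ccw = 0
    acc = 0.0      # signed progress towards a full turn
    counter = 0.0  # unsigned opposing-turn accumulation
    for d in deltas:
        if acc == 0.0 or d == 0.0 or np.sign(d) == np.sign(acc):
            acc += d
            counter = 0.0
        else:
            counter += abs(d)
            if counter > spec.opposing_tolerance_deg:
                acc = d       # restart in the new direction
                counter = 0.0
            else:
                acc += d      # tolerated wiggle
        if abs(acc) >= spec.full_turn_deg:
            if acc > 0:
                ccw += 1
            else:
                cw += 1
            acc = 0.0
            counter = 0.0
    return cw, ccw


def mobility(traj: Trajectory, speed_threshold_mm_s: float = 0.5) -> tuple[float, float]:
    """(mobile_s, immobile_s): frame intervals split by instantaneous speed.

    The threshold default is this package's convention (centroid tracks cannot
    reproduce a pixel-change mobility measure); the two durations always sum
    to the analysed duration.
    """
    if speed_threshold_mm_s <= 0:
        raise ValueError("speed threshold must be positive")
    dt = np.diff(traj.times)
    speed = np.hypot(np.diff(traj.x), np.diff(traj.y)) / dt
    mobile = float(dt[speed >= speed_threshold_mm_s].sum())
    return mobile, float(traj.duration_s - mobile)


@dataclass
class BehaviorReport:
    total_distance_mm: float
    mean_velocity_mm_s: float
    rotations_cw: int
    rotations_ccw: int
    mobile_time_s: float
    immobile_time_s: float
    bins: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "total_distance_mm": self.total_distance_mm,
            "mean_velocity_mm_s": self.mean_velocity_mm_s,
            "rotations_cw": self.rotations_cw,
            "rotations_ccw": self.rotations_ccw,
            "mobile_time_s": self.mobile_time_s,
            "immobile_time_s": self.immobile_time_s,
        }
        if self.bins is not None:
            d["bins"] = self.bins.to_dict(orient="records")
        return d


def _single_report(traj: Trajectory, rot_spec: RotationSpec,
                   speed_threshold: float) -> dict:
    dist = total_distance(traj)
    cw, ccw = count_rotations(traj, rot_spec)
    mob, immob = mobility(traj, speed_threshold)
    return {
        "total_distance_mm": dist,
        "mean_velocity_mm_s": dist / traj.duration_s,
        "rotations_cw": cw,
        "rotations_ccw": ccw,
        "mobile_time_s": mob,
        "immobile_time_s": immob,
    }


def bin_by_phase(traj: Trajectory, bin_s: float = 120.0,
                 rot_spec: RotationSpec = RotationSpec(),
                 speed_threshold_mm_s: float = 0.5) -> pd.DataFrame:
    """Metrics per consecutive ``bin_s`` bin, labelled with the bin's light phase.

    Bins tile the recording from its first timestamp; the boundary sample is
    shared between adjacent bins so per-bin distances sum exactly to the total.
    A trailing partial bin shorter than two frames is dropped.
    """
    t0 = traj.times[0]
    rows = []
    k = 0
    while True:
        lo, hi = t0 + k * bin_s, t0 + (k + 1) * bin_s
        m = (traj.times >= lo - 1e-9) & (traj.times <= hi + 1e-9)
        if m.sum() < 2:
            break
        sub = Trajectory(traj.times[m], traj.x[m], traj.y[m], traj.phase[m],
                         arena_radius=traj.arena_radius)
        # phase of the bin = label of its interior samples (majority)
        labels, counts = np.unique(sub.phase.astype(str), return_counts=True)
        rep = _single_report(sub, rot_spec, speed_threshold_mm_s)
        rep.update({"bin": k, "t_start_s": float(lo),
                    "phase": str(labels[np.argmax(counts)])})
        rows.append(rep)
        if traj.times[-1] <= hi + 1e-9:
            break
        k += 1
    cols = ["bin", "t_start_s", "phase", "total_distance_mm", "mean_velocity_mm_s",
            "rotations_cw", "rotations_ccw", "mobile_time_s", "immobile_time_s"]
    return pd.DataFrame(rows, columns=cols)


def compute_report(traj: Trajectory, rot_spec: RotationSpec = RotationSpec(),
                   speed_threshold_mm_s: float = 0.5,
                   bin_s: float | None = 120.0) -> BehaviorReport:
    """Whole-recording metrics plus the per-bin table (omit with ``bin_s=None``)."""
    rep = _single_report(traj, rot_spec, speed_threshold_mm_s)
    bins = bin_by_phase(traj, bin_s, rot_spec, speed_threshold_mm_s) \
        if bin_s is not None else None
    return BehaviorReport(bins=bins, **{k: rep[k] for k in rep})
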