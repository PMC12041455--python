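"""File formats binding the pipeline together.

Recording container: a flat little-endian float32 binary payload (channel-major,
microvolts) plus a JSON sidecar (``<stem>.json``) carrying the sampling rate,
shape, electrode layout, provenance metadata, and a SHA-256 checksum of the
payload; a checksum or shape mismatch on read is a hard error.

Spike tables and trajectories are plain CSV (comma separator, '.' decimal,
UTF-8, mandatory header); values are written with 6-decimal fixed formatting
and deterministic row order, so write-then-read round-trips at that precision.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np

from .signal import Recording, SpikeTrainSet
from .synthetic import Trajectory

__all__ = [
    "write_recording", "read_recording",
    "write_spikes", "read_spikes",
    "write_trajectory", "read_trajectory",
    "write_report", "read_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" \
        else path


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write payload to ``path`` and the JSON sidecar to ``path + '.json'``."""
    path = Path(path)
    payload = np.ascontiguousarray(rec.voltages, dtype="<f4").tobytes()
    path.write_bytes(payload)
    sidecar = {
        "fs_hz": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "layout": {str(e): list(pos) for e, pos in rec.layout.items()},
        "units": "uV",
        "metadata": rec.metadata,
        "sha256": hashlib.sha256(payload).hexdigest(),
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> Recording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    payload = path.read_bytes()
    expected = 4 * meta["n_channels"] * meta["n_samples"]
    if len(payload) != expected:
        raise ValueError(
            f"payload is {len(payload)} bytes, sidecar implies {expected}")
    if hashlib.sha256(payload).hexdigest() != meta["sha256"]:
        raise ValueError("payload checksum mismatch")
    voltages = np.frombuffer(payload, dtype="<f4").reshape(
        meta["n_channels"], meta["n_samples"])
    layout = {int(e): tuple(pos) for e, pos in meta["layout"].items()}
    return Recording(voltages.copy(), meta["fs_hz"], layout=layout,
                     metadata=meta.get("metadata", {}))


SPIKE_HEADER = ["electrode", "time_s", "amplitude_uV"]


def write_spikes(trains: SpikeTrainSet, path: str | Path) -> Path:
    """Spike CSV ordered by electrode then time, 6-decimal fixed format."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SPIKE_HEADER)
        for e in sorted(trains.times):
            for t, a in zip(trains.times[e], trains.amplitudes[e]):
                w.writerow([e, f"{t:.6f}", f"{a:.6f}"])
    return path


def read_spikes(path: str | Path, duration_s: float,
                layout: dict | None = None) -> SpikeTrainSet:
    """Read and validate a spike CSV; unsorted rows are rejected with their row number."""
    path = Path(path)
    times: dict[int, list[float]] = {}
    amps: dict[int, list[float]] = {}
    with path.open(newline="") as fh:
        r = csv.reader(fh)
        header = next(r, None)
        if header != SPIKE_HEADER:
            raise ValueError(f"bad header {header!r}, expected {SPIKE_HEADER}")
        prev: tuple[int, float] | None = None
        for i, row in enumerate(r, start=2):
            e, t, a = int(row[0]), float(row[1]), float(row[2])
            if prev is not None and (e, t) <= prev:
                raise ValueError(f"row {i}: rows not sorted by (electrode, time)")
            prev = (e, t)
            times.setdefault(e, []).append(t)
            amps.setdefault(e, []).append(a)
    kw = {"layout": layout} if layout is not None else {}
    return SpikeTrainSet({e: np.array(v) for e, v in times.items()},
                         {e: np.array(v) for e, v in amps.items()},
                         duration_s=duration_s, **kw)


TRAJ_HEADER = ["time_s", "x_mm", "y_mm", "phase"]


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Trajectory CSV; the arena radius rides along as a '#' metadata line."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if traj.arena_radius is not None:
            fh.write(f"# arena_radius_mm={traj.arena_radius:.6f}\n")
        w = csv.writer(fh)
        w.writerow(TRAJ_HEADER)
        for t, x, y, p in zip(traj.times, traj.x, traj.y, traj.phase):
            w.writerow([f"{t:.6f}", f"{x:.6f}", f"{y:.6f}", p])
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    arena = None
    with path.open(newline="") as fh:
        first = fh.readline()
        if first.startswith("#"):
            key, _, val = first[1:].strip().partition("=")
            if key.strip() == "arena_radius_mm":
                arena = float(val)
            header_line = fh.readline()
        else:
            header_line = first
        header = next(csv.reader([header_line]))
        if header != TRAJ_HEADER:
            raise ValueError(f"bad header {header!r}, expected {TRAJ_HEADER}")
        rows = list(csv.reader(fh))
    times = np.array([float(r[0]) for r in rows])
    x = np.array([float(r[1]) for r in rows])
    y = np.array([float(r[2]) for r in rows])
    phase = np.array([r[3] for r in rows], dtype=object)
    return Trajectory(times, x, y, phase, arena_radius=arena)


def write_report(report: dict, path: str | Path, config: dict | None = None,
                 seed: int | None = None) -> Path:
    """JSON report embedding the resolved configuration and seed (provenance)."""
    path = Path(path)
    doc = dict(report)
    doc["_provenance"] = {"config": config or {}, "seed": seed}
    path.write_text(json.dumps(doc, indent=1, sort_keys=True, allow_nan=True))
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
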