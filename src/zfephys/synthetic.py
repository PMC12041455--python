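"""Synthetic MEA recordings and swim trajectories with known ground truth.

The generator emulates four experimental conditions for larval-zebrafish
seizure studies — control, a hyperexcitable crispant (napb_cr), and either
group after pentylenetetrazol (PTZ) exposure — so that every downstream stage
(filtering, spike detection, burst/network-burst metrics, locomotor metrics)
can be validated by parameter recovery.

Voltage model: white Gaussian background noise of configurable RMS plus
biphasic spike templates inserted additively at ground-truth times. Tonic
firing is a gamma-renewal process with a 2 ms absolute refractory period;
bursts insert fixed-ISI spike runs; network events recruit a configurable
fraction of electrodes within a short jitter window. Head-region electrodes
carry elevated rates (and optionally amplitudes) in the crispant scenarios.

Trajectory model: a correlated random walk (wrapped-normal heading
increments, gamma step lengths) inside a circular arena with specular wall
reflection; control fish steer towards the wall tangent (thigmotaxis),
hyperactive fish swim faster with frequent sustained circling bouts, and the
PTZ effect multiplies speed by a factor decaying with a configurable
half-life.

No parameter here reproduces a measured magnitude from any specific dataset:
noise levels, amplitudes and rates are order-of-magnitude physiological
choices documented in the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .signal import Recording, grid_layout

__all__ = [
    "RecordingScenario",
    "TrajectoryScenario",
    "GroundTruth",
    "TrajectoryGroundTruth",
    "Trajectory",
    "default_head_mask",
    "spike_template",
    "generate_recording",
    "generate_trajectory",
]

SCENARIOS = ("control", "napb_cr", "control_ptz", "napb_cr_ptz")

#: Absolute refractory period for tonic firing (s).
REFRACTORY_S = 2e-3


def default_head_mask(n_rows: int = 8, n_cols: int = 8) -> frozenset[int]:
    """The 16 electrodes of the two grid columns under the head.

    With the larva mounted laterally along the array, the head overlies one
    edge of the grid; the first two columns are a reasonable default and real
    orientation varies, so this is user-overridable everywhere it is used.
    """
    layout = grid_layout(n_rows, n_cols)
    n_head_cols = max(1, n_cols // 4)
    return frozenset(e for e, (_, c) in layout.items() if c < n_head_cols)


@dataclass(frozen=True)
class RecordingScenario:
    """Generative parameters for one simulated MEA recording."""

    scenario_label: str = "control"
    n_rows: int = 8
    n_cols: int = 8
    fs: float = 12500.0
    duration_s: float = 600.0
    noise_rms: float = 3.0                 # uV
    spike_amplitude: float = 8.0           # negative peak, multiple of noise_rms
    amplitude_cv: float = 0.15             # per-spike amplitude scatter
    per_electrode_rate: float = 0.5        # tonic spikes/s
    burst_rate: float = 2.0                # bursts/min per electrode
    spikes_per_burst: int = 8
    intra_burst_isi: float = 0.05          # s
    burst_min_gap_s: float = 1.0           # enforced gap between burst episodes
    network_burst_rate: float = 0.5        # events/min, whole array
    involvement_fraction: float = 0.25
    nb_spikes_per_electrode: int = 3
    network_jitter_s: float = 0.010        # recruitment window per event
    head_mask: frozenset[int] | None = None  # None: two head-side grid columns
    head_rate_multiplier: float = 1.0
    head_amplitude_multiplier: float = 1.0
    ptz_rate_multiplier: float = 1.0
    gamma_shape: float = 2.0               # tonic renewal-ISI shape
    pink_noise_fraction: float = 0.0       # optional 1/f admixture, default off
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_label not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario_label!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 2 * 3000:
            raise ValueError("sampling rate must exceed twice the 3 kHz band edge")
        if not 0 < self.involvement_fraction <= 1:
            raise ValueError("involvement_fraction must be in (0, 1]")
        for name in ("per_electrode_rate", "burst_rate", "network_burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.head_mask is None:
            object.__setattr__(self, "head_mask",
                               default_head_mask(self.n_rows, self.n_cols))
        n = self.n_rows * self.n_cols
        if any(e < 0 or e >= n for e in self.head_mask):
            raise ValueError("head_mask outside electrode index range")
        if self.spike_amplitude < 1.0:
            warnings.warn("spike amplitude below 1 x noise RMS: spikes will be "
                          "indistinguishable from noise")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    @classmethod
    def preset(cls, label: str, seed: int = 0, **overrides) -> "RecordingScenario":
        """Named condition presets.

        napb_cr elevates head-region rate and amplitude (brain hyperactivity)
        and array-wide burst/network-burst rates; *_ptz scenarios multiply all
        rates globally and run the 30-min exposure duration.
        """
        base: dict = {"scenario_label": label, "seed": seed}
        if label == "control":
            pass
        elif label == "napb_cr":
            base.update(head_rate_multiplier=3.0, head_amplitude_multiplier=1.5,
                        burst_rate=4.0, network_burst_rate=1.5)
        elif label == "control_ptz":
            base.update(duration_s=1800.0, ptz_rate_multiplier=3.0,
                        burst_rate=4.0, network_burst_rate=2.0)
        elif label == "napb_cr_ptz":
            base.update(duration_s=1800.0, ptz_rate_multiplier=1.5,
                        head_rate_multiplier=3.0, head_amplitude_multiplier=1.5,
                        burst_rate=5.0, network_burst_rate=2.5)
        else:
            raise ValueError(f"unknown scenario {label!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Everything the generator knows that a detector must recover."""

    spike_times: dict[int, np.ndarray]
    spike_amplitudes: dict[int, np.ndarray]
    bursts: list[tuple[int, float, float, int]]        # (electrode, t0, t1, n)
    network_events: list[tuple[float, frozenset[int]]]
    rates_hz: dict[int, float]

    def validate(self) -> None:
        for e, t in self.spike_times.items():
            if np.any(np.diff(t) <= 0):
                raise AssertionError(f"electrode {e}: ground truth not increasing")

    def to_dict(self) -> dict:
        return {
            "spike_times": {str(e): np.asarray(t).tolist()
                            for e, t in self.spike_times.items()},
            "bursts": [[e, t0, t1, n] for e, t0, t1, n in self.bursts],
            "network_events": [[t, sorted(s)] for t, s in self.network_events],
            "rates_hz": {str(e): r for e, r in self.rates_hz.items()},
        }


def spike_template(amplitude_uv: float, width_ms: float = 1.0,
                   fs: float = 12500.0) -> np.ndarray:
    """Zero-mean biphasic waveform, negative lobe first, negative peak = -amplitude.

    One sine cycle of the given width: its energy sits near 1/width (1 kHz at
    the default 1 ms), inside the 200-3000 Hz detection passband, so the
    zero-phase band-pass retains most of the peak.
    """
    if width_ms <= 0:
        raise ValueError("width must be positive")
    n = max(int(round(width_ms * 1e-3 * fs)), 2)
    t = np.arange(n) / n
    return -amplitude_uv * np.sin(2 * np.pi * t)


def _renewal_train(rng: np.random.Generator, rate: float, duration: float,
                   shape: float) -> np.ndarray:
    """Gamma-renewal spike times with an absolute refractory period."""
    if rate <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate
    if mean_isi <= REFRACTORY_S:
        raise ValueError("rate incompatible with the refractory period")
    scale = (mean_isi - REFRACTORY_S) / shape
    # draw in blocks until the duration is covered
    out = []
    t = 0.0
    block = max(int(duration * rate * 1.5) + 16, 16)
    while t < duration:
        isi = REFRACTORY_S + rng.gamma(shape, scale, size=block)
        ts = t + np.cumsum(isi)
        out.append(ts)
        t = float(ts[-1])
    times = np.concatenate(out)
    return times[times < duration]


def _insert_template(trace: np.ndarray, template: np.ndarray, sample: int) -> None:
    hi = min(sample + template.size, trace.size)
    if hi > sample >= 0:
        trace[sample:hi] += template[: hi - sample]


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def generate_recording(scenario: RecordingScenario) -> tuple[Recording, GroundTruth]:
    """Simulate one multi-channel recording plus its ground truth.

    Returns voltages as float32 (channel x sample, uV). Spikes superpose
    linearly on the noise; spikes landing closer than 0.2 ms on one electrode
    are merged (the later one dropped) so ground-truth trains stay strictly
    increasing.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    n_e = sc.n_electrodes
    n_samples = int(round(sc.fs * sc.duration_s))
    layout = grid_layout(sc.n_rows, sc.n_cols)

    ptz = sc.ptz_rate_multiplier if sc.scenario_label.endswith("_ptz") else 1.0

    spike_times: dict[int, list[np.ndarray]] = {e: [] for e in range(n_e)}
    bursts: list[tuple[int, float, float, int]] = []
    rates: dict[int, float] = {}

    for e in range(n_e):
        head = e in sc.head_mask
        rate = sc.per_electrode_rate * ptz * (sc.head_rate_multiplier if head else 1.0)
        rates[e] = rate
        tonic = _renewal_train(rng, rate, sc.duration_s, sc.gamma_shape)
        spike_times[e].append(tonic)
        # per-electrode burst episodes: Poisson-timed, fixed intra-burst ISI
        br = sc.burst_rate * ptz * (sc.head_rate_multiplier if head else 1.0) / 60.0
        n_bursts = rng.poisson(br * sc.duration_s)
        burst_len = (sc.spikes_per_burst - 1) * sc.intra_burst_isi
        # place burst starts with a guaranteed inter-burst gap (and clear of
        # the trace edges) so episodes stay distinct events
        slot = burst_len + sc.burst_min_gap_s
        margin = 0.5
        free = sc.duration_s - 2 * margin - n_bursts * slot
        while n_bursts > 0 and free < 0:
            n_bursts -= 1
            free = sc.duration_s - 2 * margin - n_bursts * slot
        starts = margin + np.sort(rng.uniform(0, max(free, 0), size=n_bursts)) \
            + np.arange(n_bursts) * slot
        for t0 in starts:
            ts = t0 + np.arange(sc.spikes_per_burst) * sc.intra_burst_isi
            spike_times[e].append(ts)
            bursts.append((e, float(ts[0]), float(ts[-1]), sc.spikes_per_burst))

    # network events recruit ceil(involvement x n) electrodes within the jitter window
    network_events: list[tuple[float, frozenset[int]]] = []
    nbr = sc.network_burst_rate * ptz / 60.0
    n_events = rng.poisson(nbr * sc.duration_s)
    n_recruit = math.ceil(sc.involvement_fraction * n_e)
    for t0 in np.sort(rng.uniform(0, max(sc.duration_s - 0.1, 0), size=n_events)):
        recruited = rng.choice(n_e, size=n_recruit, replace=False)
        for e in recruited:
            offs = np.sort(rng.uniform(0, sc.network_jitter_s,
                                       size=sc.nb_spikes_per_electrode))
            spike_times[int(e)].append(t0 + offs)
        network_events.append((float(t0), frozenset(int(e) for e in recruited)))

    # merge sources per electrode, enforce strict ordering
    min_sep = 2e-4
    final_times: dict[int, np.ndarray] = {}
    final_amps: dict[int, np.ndarray] = {}
    for e in range(n_e):
        ts = np.sort(np.concatenate(spike_times[e])) if spike_times[e] else np.empty(0)
        if ts.size:
            keep = np.r_[True, np.diff(ts) >= min_sep]
            ts = ts[keep]
        head = e in sc.head_mask
        amp = sc.spike_amplitude * sc.noise_rms * \
            (sc.head_amplitude_multiplier if head else 1.0)
        amps = amp * np.maximum(
            1.0 + sc.amplitude_cv * rng.standard_normal(ts.size), 0.1)
        final_times[e] = ts
        final_amps[e] = amps

    voltages = np.empty((n_e, n_samples), dtype=np.float32)
    for e in range(n_e):
        tr = rng.standard_normal(n_samples).astype(np.float32)
        if sc.pink_noise_fraction > 0:
            p = sc.pink_noise_fraction
            tr = np.sqrt(1 - p) * tr + np.sqrt(p) * \
                _pink_noise(rng, n_samples).astype(np.float32)
        tr *= sc.noise_rms
        for t, a in zip(final_times[e], final_amps[e]):
            tpl = spike_template(a, fs=sc.fs).astype(np.float32)
            _insert_template(tr, tpl, int(round(t * sc.fs)))
        voltages[e] = tr

    meta = {"scenario": sc.scenario_label, "seed": sc.seed, "noise_rms_uV": sc.noise_rms,
            "synthetic": True}
    rec = Recording(voltages, sc.fs, layout=layout, metadata=meta)
    gt = GroundTruth(final_times, final_amps, bursts, network_events, rates)
    gt.validate()
    return rec, gt


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryScenario:
    """Generative parameters for one simulated swim trajectory.

    The default phase schedule is the dark-to-light transition protocol:
    5 min dark acclimation, then six 2-min alternating light/dark bins.
    """

    scenario_label: str = "control"
    frame_rate: float = 30.0
    arena_radius: float = 8.0              # mm; one well of a 24-well plate
    mean_speed: float = 2.0                # mm/s
    speed_cv: float = 0.6
    turn_concentration: float = 8.0        # larger -> straighter swimming
    wall_affinity: float = 0.7             # blend weight towards the wall tangent
    rotation_bias: float = 0.02            # circling-bout entries per second
    bout_duration_s: float = 2.0
    bout_turn_rate_deg_s: float = 270.0
    ptz_speed_multiplier: float = 1.0
    ptz_decay_halflife: float = 300.0      # s
    phase_schedule: tuple[tuple[str, float], ...] = (
        ("dark", 300.0),
        ("light", 120.0), ("dark", 120.0), ("light", 120.0),
        ("dark", 120.0), ("light", 120.0), ("dark", 120.0),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_label not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario_label!r}")
        if self.arena_radius <= 0:
            raise ValueError("arena_radius must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for phase, dur in self.phase_schedule:
            if phase not in ("dark", "light") or dur <= 0:
                raise ValueError("phase schedule entries must be (dark|light, s > 0)")

    @property
    def duration_s(self) -> float:
        return sum(d for _, d in self.phase_schedule)

    @classmethod
    def preset(cls, label: str, seed: int = 0, **overrides) -> "TrajectoryScenario":
        base: dict = {"scenario_label": label, "seed": seed}
        if label == "control":
            pass
        elif label == "napb_cr":
            # irregular swimming: faster, frequent circling, little wall-following
            base.update(mean_speed=4.0, rotation_bias=0.12, wall_affinity=0.1,
                        turn_concentration=3.0)
        elif label == "control_ptz":
            base.update(ptz_speed_multiplier=3.0, rotation_bias=0.08,
                        wall_affinity=0.2)
        elif label == "napb_cr_ptz":
            base.update(mean_speed=4.0, rotation_bias=0.15, wall_affinity=0.1,
                        turn_concentration=3.0, ptz_speed_multiplier=1.5)
        else:
            raise ValueError(f"unknown scenario {label!r}")
        base.update(overrides)
        return cls(**base)


@dataclass
class Trajectory:
    """Time-stamped 2-D positions (mm) with per-sample light phase labels."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    arena_radius: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.phase = np.asarray(self.phase)
        if not (len(self.times) == len(self.x) == len(self.y) == len(self.phase)):
            raise ValueError("times, x, y, phase must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TrajectoryGroundTruth:
    mean_speed_mm_s: float
    path_length_mm: float
    rotation_bouts: int
    mobile_fraction: float


def _phase_labels(schedule, times: np.ndarray) -> np.ndarray:
    bounds, labels, t = [], [], 0.0
    for phase, dur in schedule:
        t += dur
        bounds.append(t)
        labels.append(phase)
    idx = np.searchsorted(np.asarray(bounds), times, side="right")
    idx = np.minimum(idx, len(labels) - 1)
    return np.asarray(labels, dtype=object)[idx]


def generate_trajectory(scenario: TrajectoryScenario) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Correlated-random-walk swim path inside a circular arena.

    Heading increments are wrapped-normal with SD 1/sqrt(turn_concentration);
    near the wall (outer 20% of the radius) the heading is blended towards the
    local tangent with weight ``wall_affinity`` (thigmotaxis). Circling bouts
    start as a Poisson process at ``rotation_bias`` per second and impose a
    constant signed turn rate for ``bout_duration_s``. A PTZ speed multiplier
    decays towards 1 with half-life ``ptz_decay_halflife``. Wall crossings are
    handled by specular reflection of the step; all emitted positions lie
    within the arena.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    dt = 1.0 / sc.frame_rate
    n = int(round(sc.duration_s * sc.frame_rate)) + 1
    times = np.arange(n) * dt

    heading_sd = 1.0 / math.sqrt(sc.turn_concentration)
    is_ptz = sc.scenario_label.endswith("_ptz")

    x = np.empty(n)
    y = np.empty(n)
    # start mid-radius at a random angle
    ang0 = rng.uniform(0, 2 * np.pi)
    r0 = 0.5 * sc.arena_radius
    x[0], y[0] = r0 * math.cos(ang0), r0 * math.sin(ang0)
    heading = rng.uniform(0, 2 * np.pi)

    bout_left = 0.0
    bout_sign = 1.0
    n_bouts = 0
    shape = 1.0 / sc.speed_cv**2 if sc.speed_cv > 0 else None

    for i in range(1, n):
        t = times[i - 1]
        speed = sc.mean_speed
        if is_ptz and sc.ptz_speed_multiplier != 1.0:
            speed *= 1.0 + (sc.ptz_speed_multiplier - 1.0) * \
                2.0 ** (-t / sc.ptz_decay_halflife)
        if speed > 0 and shape is not None:
            step = rng.gamma(shape, speed * dt / shape)
        else:
            step = speed * dt

        if bout_left <= 0 and rng.random() < sc.rotation_bias * dt:
            bout_left = sc.bout_duration_s
            bout_sign = 1.0 if rng.random() < 0.5 else -1.0
            n_bouts += 1
        if bout_left > 0:
            heading += bout_sign * math.radians(sc.bout_turn_rate_deg_s) * dt
            bout_left -= dt
        else:
            heading += rng.normal(0.0, heading_sd)
            r = math.hypot(x[i - 1], y[i - 1])
            if r > 0.8 * sc.arena_radius and sc.wall_affinity > 0:
                # steer towards the wall tangent (counter-clockwise convention)
                tangent = math.atan2(x[i - 1], -y[i - 1]) + np.pi
                delta = math.remainder(tangent - heading, 2 * np.pi)
                heading += sc.wall_affinity * delta * dt * sc.frame_rate / 10.0

        px = x[i - 1] + step * math.cos(heading)
        py = y[i - 1] + step * math.sin(heading)
        rr = math.hypot(px, py)
        if rr > sc.arena_radius:
            # specular reflection: mirror the radial overshoot back inside
            scale = (2 * sc.arena_radius - rr) / rr
            if scale < 0:
                scale = 0.0
            px, py = px * scale, py * scale
            heading = math.atan2(py - y[i - 1], px - x[i - 1]) if step > 0 else heading
        x[i], y[i] = px, py

    phase = _phase_labels(sc.phase_schedule, times)
    traj = Trajectory(times, x, y, phase, arena_radius=sc.arena_radius,
                      metadata={"scenario": sc.scenario_label, "seed": sc.seed,
                                "synthetic": True})
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    mobile = float(np.mean(steps / dt >= 0.5)) if n > 1 else 0.0
    gt = TrajectoryGroundTruth(
        mean_speed_mm_s=path / traj.duration_s if traj.duration_s > 0 else 0.0,
        path_length_mm=path,
        rotation_bouts=n_bouts,
        mobile_fraction=mobile,
    )
    return traj, gt
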