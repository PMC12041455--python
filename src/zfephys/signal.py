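"""Raw extracellular voltage traces -> per-electrode spike trains.

Implements the acquisition pipeline used for whole-larva MEA recordings:
a 200 Hz - 3 kHz band-pass, a background-noise RMS calibration, and a
threshold-crossing spike detector at +/- 5.5 x RMS.

Amplitudes are microvolts throughout; times are seconds from recording start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "FilterSpec",
    "DetectorSpec",
    "SpikeTrainSet",
    "grid_layout",
    "bandpass",
    "estimate_background_rms",
    "detect_spikes",
]

#: Scale factor turning median(|x|) of a Gaussian into its standard deviation.
MAD_TO_SD = 1.0 / 0.6745


def grid_layout(n_rows: int = 8, n_cols: int = 8) -> dict[int, tuple[int, int]]:
    """Row-major electrode-index -> (row, col) map for an ``n_rows x n_cols`` array."""
    return {r * n_cols + c: (r, c) for r in range(n_rows) for c in range(n_cols)}


@dataclass
class Recording:
    """Multi-channel extracellular voltage matrix.

    Parameters
    ----------
    voltages : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.
    fs : float
        Sampling rate in Hz.
    layout : dict
        Electrode index -> (row, col) position on the electrode grid.
    metadata : dict
        Free-form provenance (scenario, seed, filter state, ...).
    """

    voltages: np.ndarray
    fs: float
    layout: dict[int, tuple[int, int]] = field(default_factory=grid_layout)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.layout) < self.n_channels:
            raise ValueError("layout does not cover every channel")
        positions = list(self.layout.values())
        if len(set(positions)) != len(positions):
            raise ValueError("layout assigns one grid position to several electrodes")

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification: 200 Hz - 3 kHz, 4th-order Butterworth, zero phase."""

    low_hz: float = 200.0
    high_hz: float = 3000.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz < fs / 2:
            raise ValueError(
                f"require 0 < low ({self.low_hz}) < high ({self.high_hz}) < fs/2 ({fs / 2})"
            )


@dataclass(frozen=True)
class DetectorSpec:
    """Threshold-crossing detector at ``threshold_multiplier`` x background RMS.

    ``polarity='both'`` honours the +/- of the printed threshold. The robust
    RMS uses median(|x|)/0.6745 so spikes present during calibration do not
    inflate the threshold; set ``robust=False`` for the plain RMS.
    """

    threshold_multiplier: float = 5.5
    polarity: str = "both"  # negative | positive | both
    dead_time_ms: float = 2.0
    rms_window_s: float | None = None  # None: calibrate on the whole trace
    robust: bool = True
    edge_exclude_s: float = 0.1  # drop filter transients at the trace edges

    def __post_init__(self) -> None:
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.dead_time_ms < 0:
            raise ValueError("dead_time_ms must be >= 0")
        if self.polarity not in ("negative", "positive", "both"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class SpikeTrainSet:
    """Per-electrode spike times (s) and signed peak amplitudes (uV)."""

    times: dict[int, np.ndarray]
    amplitudes: dict[int, np.ndarray]
    duration_s: float
    layout: dict[int, tuple[int, int]] = field(default_factory=grid_layout)

    def __post_init__(self) -> None:
        for e, t in self.times.items():
            t = np.asarray(t, dtype=float)
            self.times[e] = t
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"electrode {e}: spike times not strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > self.duration_s):
                raise ValueError(f"electrode {e}: spike times outside [0, duration]")
            a = self.amplitudes.get(e)
            if a is None:
                self.amplitudes[e] = np.full(t.size, np.nan)
            elif len(a) != t.size:
                raise ValueError(f"electrode {e}: amplitude/time length mismatch")

    @property
    def electrodes(self) -> list[int]:
        return sorted(self.times)

    @property
    def n_electrodes(self) -> int:
        """Size of the array (layout), not just electrodes with spikes."""
        return len(self.layout)

    def n_spikes(self, electrode: int) -> int:
        return self.times.get(electrode, np.empty(0)).size

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.times.values()))

    def restrict(self, t0: float, t1: float) -> "SpikeTrainSet":
        """Spikes with t0 <= t < t1, re-referenced to t0."""
        times, amps = {}, {}
        for e, t in self.times.items():
            m = (t >= t0) & (t < t1)
            times[e] = t[m] - t0
            amps[e] = np.asarray(self.amplitudes[e])[m]
        return SpikeTrainSet(times, amps, duration_s=t1 - t0, layout=self.layout)


def _sos(spec: FilterSpec, fs: float) -> np.ndarray:
    return sps.butter(spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
                      fs=fs, output="sos")


def bandpass(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Band-pass filter every channel; zero-phase by default so spike times do not shift."""
    spec.validate(recording.fs)
    sos = _sos(spec, recording.fs)
    out = np.empty_like(recording.voltages, dtype=np.float64)
    for ch in range(recording.n_channels):
        x = recording.voltages[ch].astype(np.float64)
        out[ch] = sps.sosfiltfilt(sos, x) if spec.zero_phase else sps.sosfilt(sos, x)
    meta = dict(recording.metadata)
    meta["filtered"] = {"low_hz": spec.low_hz, "high_hz": spec.high_hz,
                        "order": spec.order, "zero_phase": spec.zero_phase}
    return Recording(out.astype(recording.voltages.dtype), recording.fs,
                     layout=recording.layout, metadata=meta)


def estimate_background_rms(trace: np.ndarray, spec: DetectorSpec = DetectorSpec(),
                            fs: float | None = None) -> float:
    """Background-noise RMS of one channel, in the trace's units.

    The default robust estimator, median(|x|)/0.6745, matches the Gaussian SD
    while ignoring sparse large excursions (spikes) present during calibration.
    With ``robust=False`` this is the plain root mean square.
    """
    x = np.asarray(trace, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty trace")
    if spec.rms_window_s is not None:
        if fs is None:
            raise ValueError("fs required when rms_window_s is set")
        n = int(round(spec.rms_window_s * fs))
        if x.size < n:
            raise ValueError("trace shorter than the calibration window")
        x = x[:n]
    if spec.robust:
        return float(np.median(np.abs(x)) * MAD_TO_SD)
    return float(np.sqrt(np.mean(x**2)))


def _excursion_events(x: np.ndarray, threshold: float, polarity: str):
    """(peak_index, signed_peak) for each contiguous excursion beyond the threshold."""
    if polarity == "negative":
        over = x < -threshold
    elif polarity == "positive":
        over = x > threshold
    else:
        over = np.abs(x) > threshold
    if not over.any():
        return np.empty(0, dtype=int), np.empty(0)
    edges = np.diff(over.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if over[0]:
        starts = np.r_[0, starts]
    if over[-1]:
        ends = np.r_[ends, over.size]
    idx = np.empty(starts.size, dtype=int)
    amp = np.empty(starts.size)
    for k, (s, e) in enumerate(zip(starts, ends)):
        seg = x[s:e]
        j = int(np.argmax(np.abs(seg)))
        idx[k] = s + j
        amp[k] = seg[j]
    return idx, amp


def _merge_dead_time(idx: np.ndarray, amp: np.ndarray, dead_samples: int):
    """Merge events closer than the dead time, keeping the larger |amplitude|
    (ties go to the earlier event)."""
    if idx.size <= 1 or dead_samples <= 0:
        return idx, amp
    keep_idx, keep_amp = [idx[0]], [amp[0]]
    for i, a in zip(idx[1:], amp[1:]):
        if i - keep_idx[-1] < dead_samples:
            if abs(a) > abs(keep_amp[-1]):
                keep_idx[-1], keep_amp[-1] = i, a
        else:
            keep_idx.append(i)
            keep_amp.append(a)
    return np.array(keep_idx), np.array(keep_amp)


def detect_spikes(recording: Recording,
                  filter_spec: FilterSpec | None = FilterSpec(),
                  det_spec: DetectorSpec = DetectorSpec(),
                  rms_override: dict[int, float] | float | None = None) -> SpikeTrainSet:
    """Threshold-crossing spike detection on every channel.

    Per channel the threshold is ``threshold_multiplier x background RMS``; an
    event is a contiguous excursion beyond the (signed) threshold, timed at its
    extreme sample; events closer than the dead time are merged keeping the
    larger excursion. Pass ``filter_spec=None`` for a recording that is already
    band-passed. ``rms_override`` substitutes an external noise calibration
    (single value or per-electrode map), e.g. from a separate quiescent segment.
    """
    rec = bandpass(recording, filter_spec) if filter_spec is not None else recording
    edge = int(round(det_spec.edge_exclude_s * rec.fs))
    dead = int(round(det_spec.dead_time_ms * 1e-3 * rec.fs))
    times: dict[int, np.ndarray] = {}
    amps: dict[int, np.ndarray] = {}
    for ch in range(rec.n_channels):
        x = rec.voltages[ch].astype(np.float64)
        if rms_override is None:
            rms = estimate_background_rms(x, det_spec, fs=rec.fs)
        elif isinstance(rms_override, dict):
            rms = float(rms_override[ch])
        else:
            rms = float(rms_override)
        if rms == 0:
            warnings.warn(f"electrode {ch}: zero RMS estimate, channel skipped")
            times[ch] = np.empty(0)
            amps[ch] = np.empty(0)
            continue
        thr = det_spec.threshold_multiplier * rms
        idx, amp = _excursion_events(x, thr, det_spec.polarity)
        if edge > 0 and idx.size:
            m = (idx >= edge) & (idx < rec.n_samples - edge)
            idx, amp = idx[m], amp[m]
        idx, amp = _merge_dead_time(idx, amp, dead)
        times[ch] = idx / rec.fs
        amps[ch] = amp
    return SpikeTrainSet(times, amps, duration_s=rec.duration_s, layout=rec.layout)
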