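"""Spike-train metrics for whole-larva MEA recordings.

Implements the metric layer applied to detected spikes: the 5-min active
analysis window, the 5 spikes/min active-electrode rule, the weighted mean
firing rate (mean over active electrodes only), single-electrode bursts
(>= 5 consecutive spikes, every ISI < 100 ms), pooled network bursts
(>= 5 pooled spikes, pooled ISI < 100 ms, >= 10% electrode involvement),
the spike-amplitude grid, raster export, and a head-region hyperactivity
classification.

The head/trunk hyperactivity criterion (``classify_brain_hyperactivity``) is
this package's own convention — no published quantitative rule exists for it;
the default ratio threshold of 2.0 is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import SpikeTrainSet

__all__ = [
    "MetricSpec",
    "Burst",
    "NetworkBurst",
    "HeadActivityResult",
    "NeuralMetricReport",
    "select_analysis_window",
    "classify_active",
    "weighted_mean_firing_rate",
    "detect_bursts",
    "detect_network_bursts",
    "burst_frequency",
    "network_burst_frequency",
    "amplitude_heatmap",
    "raster",
    "classify_brain_hyperactivity",
    "compute_report",
]

#: Numerical tie tolerance (s) for the strict ISI comparison: an ISI equal to
#: the cut-off up to 1 ns counts as *at* the cut-off, hence not qualifying.
ISI_TIE_TOL = 1e-9


@dataclass(frozen=True)
class MetricSpec:
    active_threshold: float = 5.0        # spikes/min, inclusive
    burst_min_spikes: int = 5
    burst_max_isi_s: float = 0.100       # strict "less than"
    nb_min_spikes: int = 5
    nb_max_isi_s: float = 0.100
    nb_min_involvement: float = 0.10     # fraction of all electrodes, inclusive
    nb_denominator_active_only: bool = False
    analysis_window_s: float = 300.0
    head_ratio_threshold: float = 2.0    # package convention, not from any protocol

    def __post_init__(self) -> None:
        if self.burst_min_spikes < 1 or self.nb_min_spikes < 1:
            raise ValueError("minimum spike counts must be >= 1")
        if self.burst_max_isi_s <= 0 or self.nb_max_isi_s <= 0:
            raise ValueError("ISI limits must be > 0")
        if not 0 < self.nb_min_involvement <= 1:
            raise ValueError("involvement fraction must be in (0, 1]")


@dataclass(frozen=True)
class Burst:
    electrode: int
    t_start: float
    t_end: float
    n_spikes: int


@dataclass(frozen=True)
class NetworkBurst:
    t_start: float
    t_end: float
    electrodes: frozenset[int]
    n_spikes: int
    involvement: float


@dataclass(frozen=True)
class HeadActivityResult:
    """``hyperactive`` is None when either region has no active electrode."""

    hyperactive: bool | None
    ratio: float
    head_wmfr: float
    trunk_wmfr: float


def _isi_ok(isi: np.ndarray, max_isi: float) -> np.ndarray:
    return isi < max_isi - ISI_TIE_TOL


def select_analysis_window(trains: SpikeTrainSet,
                           spec: MetricSpec = MetricSpec()) -> tuple[float, float]:
    """Contiguous window of ``analysis_window_s`` maximizing total spike count.

    Candidate starts lie on a 1 s lattice; ties break to the earliest start,
    so a uniformly active recording is analysed from t = 0.
    """
    w = spec.analysis_window_s
    if trains.duration_s < w:
        raise ValueError(
            f"recording ({trains.duration_s} s) shorter than analysis window ({w} s)")
    pooled = np.sort(np.concatenate([t for t in trains.times.values()] or [np.empty(0)]))
    starts = np.arange(0.0, trains.duration_s - w + 1e-9, 1.0)
    # count of spikes in [t0, t0 + w)
    counts = np.searchsorted(pooled, starts + w, side="left") - \
        np.searchsorted(pooled, starts, side="left")
    t0 = float(starts[int(np.argmax(counts))])
    return t0, t0 + w


def classify_active(times: np.ndarray | int, duration_s: float,
                    spec: MetricSpec = MetricSpec()) -> bool:
    """Active-electrode rule: firing rate >= 5 spikes/min (inclusive)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = times if isinstance(times, (int, np.integer)) else np.asarray(times).size
    rate_per_min = n / (duration_s / 60.0)
    return bool(rate_per_min >= spec.active_threshold * (1 - 1e-12))


def _rates(trains: SpikeTrainSet) -> dict[int, float]:
    return {e: trains.n_spikes(e) / trains.duration_s for e in trains.layout}


def _active_set(trains: SpikeTrainSet, spec: MetricSpec) -> set[int]:
    return {e for e in trains.layout
            if classify_active(trains.n_spikes(e), trains.duration_s, spec)}


def weighted_mean_firing_rate(trains: SpikeTrainSet,
                              spec: MetricSpec = MetricSpec()) -> float:
    """Mean firing rate (Hz) over active electrodes only; NaN if none is active.

    NaN (not 0) distinguishes a silent well from a measured low rate.
    """
    active = _active_set(trains, spec)
    if not active:
        return float("nan")
    rates = _rates(trains)
    return float(np.mean([rates[e] for e in active]))


def detect_bursts(times: np.ndarray, spec: MetricSpec = MetricSpec(),
                  electrode: int = 0) -> list[Burst]:
    """Maximal runs of >= ``burst_min_spikes`` consecutive spikes, every ISI < cut-off.

    Runs are maximal by construction (split exactly at non-qualifying ISIs),
    hence disjoint and ordered.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    if t.size < spec.burst_min_spikes:
        return []
    ok = _isi_ok(np.diff(t), spec.burst_max_isi_s)
    bursts = []
    run_start = 0
    for i in range(t.size):
        last = i == t.size - 1
        if last or not ok[i]:
            run_len = i - run_start + 1
            if run_len >= spec.burst_min_spikes:
                bursts.append(Burst(electrode, float(t[run_start]), float(t[i]), run_len))
            run_start = i + 1
    return bursts


def detect_bursts_all(trains: SpikeTrainSet, spec: MetricSpec = MetricSpec(),
                      active_only: bool = True) -> list[Burst]:
    """Bursts across the array; by default only from active electrodes."""
    active = _active_set(trains, spec) if active_only else set(trains.layout)
    out: list[Burst] = []
    for e in sorted(trains.times):
        if e in active:
            out.extend(detect_bursts(trains.times[e], spec, electrode=e))
    return sorted(out, key=lambda b: (b.t_start, b.electrode))


def detect_network_bursts(trains: SpikeTrainSet,
                          spec: MetricSpec = MetricSpec()) -> list[NetworkBurst]:
    """Pooled-train network bursts.

    All spikes are pooled into one time-sorted sequence; maximal runs with
    pooled ISI < cut-off and length >= ``nb_min_spikes`` qualify when the
    contributing-electrode fraction meets ``nb_min_involvement`` and at least
    two distinct electrodes contribute. The involvement denominator is the
    whole array by default (``nb_denominator_active_only`` switches it to the
    active set).
    """
    pairs = [(t, e) for e, ts in trains.times.items() for t in ts]
    if not pairs:
        return []
    pairs.sort()
    times = np.array([p[0] for p in pairs])
    elecs = np.array([p[1] for p in pairs])
    if spec.nb_denominator_active_only:
        denom = max(len(_active_set(trains, spec)), 1)
    else:
        denom = trains.n_electrodes
    ok = _isi_ok(np.diff(times), spec.nb_max_isi_s)
    out: list[NetworkBurst] = []
    run_start = 0
    for i in range(times.size):
        last = i == times.size - 1
        if last or not ok[i]:
            run_len = i - run_start + 1
            if run_len >= spec.nb_min_spikes:
                contrib = frozenset(int(e) for e in elecs[run_start:i + 1])
                inv = len(contrib) / denom
                if len(contrib) >= 2 and inv >= spec.nb_min_involvement - 1e-12:
                    out.append(NetworkBurst(float(times[run_start]), float(times[i]),
                                            contrib, run_len, inv))
            run_start = i + 1
    return out


def burst_frequency(bursts: list, window_s: float) -> float:
    if window_s <= 0:
        raise ValueError("window must be positive")
    return len(bursts) / window_s


def network_burst_frequency(nbs: list, window_s: float) -> float:
    return burst_frequency(nbs, window_s)


def amplitude_heatmap(trains: SpikeTrainSet) -> np.ndarray:
    """Mean |spike amplitude| (uV) per electrode on its grid cell; NaN if silent."""
    n_rows = max(r for r, _ in trains.layout.values()) + 1
    n_cols = max(c for _, c in trains.layout.values()) + 1
    grid = np.full((n_rows, n_cols), np.nan)
    for e, (r, c) in trains.layout.items():
        a = np.asarray(trains.amplitudes.get(e, ()))
        if a.size:
            grid[r, c] = float(np.mean(np.abs(a)))
    return grid


def raster(trains: SpikeTrainSet) -> pd.DataFrame:
    """Flat (electrode, time_s) event table ordered by electrode then time."""
    rows = [(e, float(t)) for e in sorted(trains.times) for t in trains.times[e]]
    return pd.DataFrame(rows, columns=["electrode", "time_s"]).astype(
        {"electrode": int, "time_s": float})


def classify_brain_hyperactivity(trains: SpikeTrainSet, head_mask: set[int],
                                 spec: MetricSpec = MetricSpec()) -> HeadActivityResult:
    """Head-region hyperactivity: head WMFR >= threshold x trunk WMFR.

    Both rates are restricted to active electrodes within each region; a region
    without active electrodes makes the status indeterminate (None), which is
    distinct from "not hyperactive".
    """
    head_mask = set(head_mask)
    all_e = set(trains.layout)
    if not head_mask or not head_mask < all_e:
        raise ValueError("head_mask must be a non-empty strict subset of the electrodes")
    trunk = all_e - head_mask
    rates = _rates(trains)
    active = _active_set(trains, spec)
    head_active = [rates[e] for e in head_mask & active]
    trunk_active = [rates[e] for e in trunk & active]
    head_wmfr = float(np.mean(head_active)) if head_active else float("nan")
    trunk_wmfr = float(np.mean(trunk_active)) if trunk_active else float("nan")
    if not head_active or not trunk_active:
        return HeadActivityResult(None, float("nan"), head_wmfr, trunk_wmfr)
    ratio = head_wmfr / trunk_wmfr
    return HeadActivityResult(bool(ratio >= spec.head_ratio_threshold), ratio,
                              head_wmfr, trunk_wmfr)


@dataclass
class NeuralMetricReport:
    window: tuple[float, float]
    per_electrode_rate_hz: dict[int, float]
    active_electrodes: list[int]
    weighted_mean_firing_rate_hz: float
    n_bursts: int
    burst_frequency_hz: float
    n_network_bursts: int
    network_burst_frequency_hz: float
    head_activity: HeadActivityResult | None = None
    spec: MetricSpec = field(default_factory=MetricSpec)

    def to_dict(self) -> dict:
        d = {
            "window_s": list(self.window),
            "per_electrode_rate_hz": {str(k): v for k, v in
                                      sorted(self.per_electrode_rate_hz.items())},
            "active_electrodes": self.active_electrodes,
            "n_active_electrodes": len(self.active_electrodes),
            "weighted_mean_firing_rate_hz": self.weighted_mean_firing_rate_hz,
            "n_bursts": self.n_bursts,
            "burst_frequency_hz": self.burst_frequency_hz,
            "n_network_bursts": self.n_network_bursts,
            "network_burst_frequency_hz": self.network_burst_frequency_hz,
        }
        if self.head_activity is not None:
            d["head_hyperactive"] = self.head_activity.hyperactive
            d["head_trunk_ratio"] = self.head_activity.ratio
        return d


def compute_report(trains: SpikeTrainSet, spec: MetricSpec = MetricSpec(),
                   head_mask: set[int] | None = None,
                   window: tuple[float, float] | None = None) -> NeuralMetricReport:
    """Full metric report over the selected (or given) analysis window."""
    if window is None:
        window = select_analysis_window(trains, spec)
    sub = trains.restrict(*window)
    w = window[1] - window[0]
    bursts = detect_bursts_all(sub, spec)
    nbs = detect_network_bursts(sub, spec)
    head = classify_brain_hyperactivity(sub, head_mask, spec) if head_mask else None
    return NeuralMetricReport(
        window=window,
        per_electrode_rate_hz=_rates(sub),
        active_electrodes=sorted(_active_set(sub, spec)),
        weighted_mean_firing_rate_hz=weighted_mean_firing_rate(sub, spec),
        n_bursts=len(bursts),
        burst_frequency_hz=burst_frequency(bursts, w),
        n_network_bursts=len(nbs),
        network_burst_frequency_hz=network_burst_frequency(nbs, w),
        head_activity=head,
        spec=spec,
    )
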