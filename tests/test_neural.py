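"""Spike-train metric layer: activity rule, WMFR, bursts, network bursts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_bursts, brute_force_network_bursts
from conftest import trains_from_times
from zfephys import neural
from zfephys.neural import (MetricSpec, amplitude_heatmap,
                            classify_active, classify_brain_hyperactivity,
                            burst_frequency, compute_report, detect_bursts,
                            detect_network_bursts, raster,
                            select_analysis_window, weighted_mean_firing_rate)

SPEC = MetricSpec()


class TestAnalysisWindow:
    def test_uniform_activity_earliest_window(self):
        times = {0: np.arange(0.5, 600.0, 1.0)}
        trains = trains_from_times(times, 600.0)
        assert select_analysis_window(trains, SPEC) == (0.0, 300.0)

    def test_window_tracks_activity_epoch(self):
        """All spikes between minutes 3 and 8 -> window [180, 480]."""
        times = {0: np.arange(180.0, 480.0, 0.5)}
        trains = trains_from_times(times, 600.0)
        assert select_analysis_window(trains, SPEC) == (180.0, 480.0)

    def test_recording_shorter_than_window_rejected(self):
        trains = trains_from_times({0: [1.0, 2.0]}, 240.0)
        with pytest.raises(ValueError, match="shorter"):
            select_analysis_window(trains, SPEC)

    def test_brute_force_agreement(self):
        """1 s lattice scan agrees with an independent exhaustive count."""
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 600, 400))
        trains = trains_from_times({0: times}, 600.0)
        t0, t1 = select_analysis_window(trains, SPEC)
        best = max(range(301), key=lambda s: np.sum((times >= s) & (times < s + 300)))
        assert t0 == float(best)


class TestActiveRule:
    @pytest.mark.parametrize("n, active", [(0, False), (4, False),
                                           (5, True), (6, True)])
    def test_threshold_at_5_per_minute(self, n, active):
        assert classify_active(n, 60.0, SPEC) is active

    def test_rate_scales_with_duration(self):
        # 25 spikes over 300 s = 5/min: still active (inclusive threshold)
        assert classify_active(25, 300.0, SPEC)
        assert not classify_active(24, 300.0, SPEC)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            classify_active(3, 0.0, SPEC)


class TestWmfr:
    def test_mean_of_active_only(self):
        times = {0: np.arange(0, 300, 1.0),        # 1 Hz
                 1: np.arange(0, 300, 1 / 3)}      # 3 Hz
        trains = trains_from_times(times, 300.0)
        assert weighted_mean_firing_rate(trains, SPEC) == pytest.approx(2.0)

    def test_single_active_electrode(self):
        trains = trains_from_times({0: np.linspace(1, 299, 30)}, 300.0)
        assert weighted_mean_firing_rate(trains, SPEC) == pytest.approx(0.1)

    def test_silent_electrodes_do_not_dilute(self):
        times = {0: np.arange(0, 300, 1.0), 1: np.arange(0.5, 300, 1 / 3)}
        base = weighted_mean_firing_rate(trains_from_times(times, 300.0), SPEC)
        times.update({e: [float(e)] for e in range(10, 20)})  # sub-threshold
        aug = weighted_mean_firing_rate(trains_from_times(times, 300.0), SPEC)
        assert aug == pytest.approx(base)

    def test_no_active_electrodes_is_missing_not_zero(self):
        trains = trains_from_times({0: [1.0, 2.0]}, 300.0)
        assert np.isnan(weighted_mean_firing_rate(trains, SPEC))


class TestBurstDetection:
    def test_five_spikes_at_50ms_is_one_burst(self):
        bursts = detect_bursts(np.arange(5) * 0.05, SPEC)
        assert len(bursts) == 1 and bursts[0].n_spikes == 5

    def test_four_spikes_is_no_burst(self):
        assert detect_bursts(np.arange(4) * 0.05, SPEC) == []

    def test_isi_at_120ms_is_no_burst(self):
        assert detect_bursts(np.arange(10) * 0.120, SPEC) == []

    def test_isi_exactly_100ms_is_no_burst(self):
        """The ISI rule is strictly 'less than' 100 ms."""
        assert detect_bursts(np.arange(10) * 0.100, SPEC) == []

    def test_two_runs_example(self):
        t = np.array([0, .05, .10, .15, .20, .60, .65, .70, .75, .80])
        bursts = detect_bursts(t, SPEC)
        assert [(b.n_spikes, b.t_start) for b in bursts] == [(5, 0.0), (5, 0.60)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(np.array([0.2, 0.1, 0.3]), SPEC)

    def test_burst_structure_disjoint_and_maximal(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 5, 200))
        t = t[np.r_[True, np.diff(t) > 0]]
        bursts = detect_bursts(t, SPEC)
        for a, b in zip(bursts, bursts[1:]):
            assert a.t_end < b.t_start
        assert bursts == [neural.Burst(0, t0, t1, n)
                          for t0, t1, n in brute_force_bursts(t)]


class TestNetworkBursts:
    def synchronous_trains(self, n_contributing, n_spikes_each=5, width=0.05):
        times = {e: np.linspace(0.001 * e, 0.001 * e + width, n_spikes_each)
                 for e in range(n_contributing)}
        return trains_from_times(times, 60.0)  # 8x8 layout: 64 electrodes

    def test_seven_of_64_qualifies(self):
        nbs = detect_network_bursts(self.synchronous_trains(7), SPEC)
        assert len(nbs) == 1
        assert nbs[0].involvement == pytest.approx(7 / 64)

    def test_six_of_64_below_involvement(self):
        assert detect_network_bursts(self.synchronous_trains(6), SPEC) == []

    def test_single_electrode_never_network_burst(self):
        trains = trains_from_times({0: np.arange(20) * 0.01}, 60.0)
        assert detect_network_bursts(trains, SPEC) == []

    def test_active_only_denominator_flag(self):
        spec = MetricSpec(nb_denominator_active_only=True)
        nbs = detect_network_bursts(self.synchronous_trains(6), spec)
        assert len(nbs) == 1 and nbs[0].involvement == pytest.approx(1.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.data())
def test_burst_detectors_match_brute_force(data):
    """Oracle equivalence on random small instances (<= 5 electrodes,
    <= 50 spikes): both detectors agree exactly with exhaustive enumeration."""
    n_e = data.draw(st.integers(1, 5))
    trains = {}
    for e in range(n_e):
        n = data.draw(st.integers(0, 10))
        raw = data.draw(st.lists(st.floats(0, 3), min_size=n, max_size=n))
        t = np.unique(np.round(np.asarray(raw), 4))
        trains[e] = t
    ts = trains_from_times(trains, 10.0, n_rows=4, n_cols=4)
    spec = MetricSpec(nb_min_involvement=0.10)
    for e, t in trains.items():
        got = [(b.t_start, b.t_end, b.n_spikes) for b in detect_bursts(t, spec)]
        assert got == brute_force_bursts(t)
    got_nb = [(nb.t_start, nb.t_end, nb.n_spikes, nb.electrodes)
              for nb in detect_network_bursts(ts, spec)]
    assert got_nb == brute_force_network_bursts(trains, n_electrodes=16)


class TestFrequenciesAndViews:
    def test_burst_frequency_arithmetic(self):
        assert burst_frequency([1] * 30, 300.0) == pytest.approx(0.1)
        assert burst_frequency([], 300.0) == 0.0
        t = np.array([0, .05, .10, .15, .20, .60, .65, .70, .75, .80])
        assert burst_frequency(detect_bursts(t, SPEC), 300.0) == \
            pytest.approx(2 / 300)

    def test_heatmap_no_spikes_all_missing(self):
        grid = amplitude_heatmap(trains_from_times({}, 60.0))
        assert grid.shape == (8, 8) and np.all(np.isnan(grid))

    def test_heatmap_mean_absolute_amplitude(self):
        trains = trains_from_times({9: [1.0, 2.0]}, 60.0)
        trains.amplitudes[9] = np.array([-10.0, -20.0])
        grid = amplitude_heatmap(trains)
        r, c = trains.layout[9]
        assert grid[r, c] == pytest.approx(15.0)
        assert np.isnan(np.delete(grid.ravel(), r * 8 + c)).all()

    def test_raster_round_trip(self):
        rng = np.random.default_rng(2)
        times = {e: np.sort(rng.uniform(0, 60, rng.integers(1, 20)))
                 for e in range(5)}
        trains = trains_from_times(times, 60.0)
        df = raster(trains)
        assert len(df) == trains.total_spikes()
        for e in times:
            got = df.loc[df.electrode == e, "time_s"].to_numpy()
            assert np.allclose(got, times[e])

    def test_raster_empty(self):
        assert raster(trains_from_times({}, 60.0)).empty


class TestHeadHyperactivity:
    def grid_trains(self, head_rate, trunk_rate):
        head = {e for e in range(64) if e % 8 < 2}
        times = {}
        for e in range(64):
            r = head_rate if e in head else trunk_rate
            if r > 0:
                times[e] = np.arange(0.001 * e, 60.0, 1.0 / r)
        return trains_from_times(times, 60.0), head

    def test_uniform_rates_not_hyperactive(self):
        trains, head = self.grid_trains(2.0, 2.0)
        res = classify_brain_hyperactivity(trains, head, SPEC)
        assert res.hyperactive is False
        assert res.ratio == pytest.approx(1.0, rel=0.02)

    def test_head_4x_trunk_1x_hyperactive(self):
        trains, head = self.grid_trains(4.0, 1.0)
        res = classify_brain_hyperactivity(trains, head, SPEC)
        assert res.hyperactive is True
        assert res.ratio == pytest.approx(4.0, rel=0.05)

    def test_silent_fish_indeterminate(self):
        trains, head = self.grid_trains(0.0, 0.0)
        res = classify_brain_hyperactivity(trains, head, SPEC)
        assert res.hyperactive is None

    def test_bad_mask_rejected(self):
        trains, _ = self.grid_trains(1.0, 1.0)
        with pytest.raises(ValueError):
            classify_brain_hyperactivity(trains, set(), SPEC)
        with pytest.raises(ValueError):
            classify_brain_hyperactivity(trains, set(range(64)), SPEC)


def test_wmfr_scales_with_rate():
    """Doubling every electrode's Poisson rate doubles WMFR within sampling
    error."""
    rng = np.random.default_rng(77)
    def poisson_trains(rate):
        times = {e: np.sort(rng.uniform(0, 300.0, rng.poisson(rate * 300)))
                 for e in range(16)}
        return trains_from_times(
            {e: np.unique(t) for e, t in times.items()}, 300.0, n_rows=4, n_cols=4)
    w1 = weighted_mean_firing_rate(poisson_trains(1.0), SPEC)
    w2 = weighted_mean_firing_rate(poisson_trains(2.0), SPEC)
    assert w2 / w1 == pytest.approx(2.0, rel=0.05)


def test_compute_report_consistency():
    """Report invariants: WMFR = mean of active rates, frequencies = count/window."""
    rng = np.random.default_rng(10)
    times = {e: np.unique(np.sort(rng.uniform(0, 600, 900))) for e in range(8)}
    trains = trains_from_times(times, 600.0)
    rep = compute_report(trains, SPEC)
    w = rep.window[1] - rep.window[0]
    assert w == SPEC.analysis_window_s
    active_rates = [rep.per_electrode_rate_hz[e] for e in rep.active_electrodes]
    assert rep.weighted_mean_firing_rate_hz == pytest.approx(np.mean(active_rates))
    assert rep.burst_frequency_hz == pytest.approx(rep.n_bursts / w)
    assert rep.network_burst_frequency_hz == pytest.approx(rep.n_network_bursts / w)
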