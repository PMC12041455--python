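"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the burst / network-burst definitions by
exhaustive enumeration of candidate runs, so they share no code path with the
package's detectors.
"""

from __future__ import annotations

import numpy as np

ISI_TOL = 1e-9


def brute_force_bursts(times, min_spikes=5, max_isi=0.100):
    """All maximal runs of >= min_spikes consecutive spikes with every ISI < max_isi."""
    t = np.asarray(times, dtype=float)
    n = t.size
    qual = [t[i + 1] - t[i] < max_isi - ISI_TOL for i in range(n - 1)]
    out = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            if all(qual[i:j]):
                left_max = i == 0 or not qual[i - 1]
                right_max = j == n - 1 or not qual[j]
                if left_max and right_max:
                    out.append((float(t[i]), float(t[j]), j - i + 1))
    return out


def brute_force_network_bursts(trains: dict, n_electrodes: int, min_spikes=5,
                               max_isi=0.100, min_involvement=0.10):
    """Qualifying maximal pooled runs with involvement and >= 2 electrodes."""
    pairs = sorted((float(t), int(e)) for e, ts in trains.items() for t in ts)
    t = np.array([p[0] for p in pairs])
    e = np.array([p[1] for p in pairs], dtype=int)
    n = t.size
    qual = [t[i + 1] - t[i] < max_isi - ISI_TOL for i in range(n - 1)]
    out = []
    for i in range(n):
        for j in range(i + min_spikes - 1, n):
            if all(qual[i:j]):
                left_max = i == 0 or not qual[i - 1]
                right_max = j == n - 1 or not qual[j]
                if left_max and right_max:
                    contrib = set(e[i:j + 1].tolist())
                    inv = len(contrib) / n_electrodes
                    if len(contrib) >= 2 and inv >= min_involvement - 1e-12:
                        out.append((float(t[i]), float(t[j]), j - i + 1,
                                    frozenset(contrib)))
    return out
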