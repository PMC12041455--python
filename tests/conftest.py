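import numpy as np
import pytest

from zfephys import signal as sig
from zfephys import synthetic


@pytest.fixture(scope="session")
def quiet_recording():
    """Pure-noise control recording, 4 electrodes, 20 s, no spikes."""
    sc = synthetic.RecordingScenario.preset(
        "control", seed=101, duration_s=20.0, n_rows=2, n_cols=2,
        per_electrode_rate=0.0, burst_rate=0.0, network_burst_rate=0.0)
    return synthetic.generate_recording(sc)


@pytest.fixture(scope="session")
def tonic_recording():
    """Moderate tonic firing on 4 electrodes, 60 s."""
    sc = synthetic.RecordingScenario.preset(
        "control", seed=202, duration_s=60.0, n_rows=2, n_cols=2,
        per_electrode_rate=1.0, burst_rate=0.0, network_burst_rate=0.0)
    return synthetic.generate_recording(sc)


def trains_from_times(times_by_electrode: dict, duration_s: float,
                      n_rows: int = 8, n_cols: int = 8) -> sig.SpikeTrainSet:
    """SpikeTrainSet from raw time dicts on a full grid layout."""
    layout = sig.grid_layout(n_rows, n_cols)
    times = {e: np.asarray(t, dtype=float) for e, t in times_by_electrode.items()}
    amps = {e: np.full(len(t), -10.0) for e, t in times.items()}
    return sig.SpikeTrainSet(times, amps, duration_s=duration_s, layout=layout)
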