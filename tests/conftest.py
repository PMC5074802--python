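import numpy as np
import pytest

from cortmap.trace import SweepTrace

FS = 2000.0  # Hz
ONSET = 100.0  # ms
N = 500  # 250 ms traces


def make_sweep(samples, fs=FS, onset=ONSET, vhold=-70.0):
    return SweepTrace(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=fs,
        stim_onset=onset,
        holding_potential=vhold,
    )


def constant_sweeps(value, n_reps=3, n=N, fs=FS, onset=ONSET):
    """Reps with zero baseline and `value` from stimulus onset onward."""
    onset_idx = int(round(onset * fs / 1000.0))
    x = np.zeros(n)
    x[onset_idx:] = value
    return [make_sweep(x, fs, onset) for _ in range(n_reps)]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sweep_factory():
    return make_sweep
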