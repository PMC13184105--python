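import numpy as np
import pytest

from tmstheta.timefreq import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, sfreq=500.0, tmin=-1000.0, channels=None, **kw):
    """EpochSet from a raw array with a uniform time axis starting at tmin."""
    data = np.asarray(data, dtype=float)
    n_s = data.shape[-1]
    times = tmin + np.arange(n_s) / sfreq * 1000.0
    if channels is None:
        channels = [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data=data, channels=channels, sfreq=sfreq, times=times, **kw)


@pytest.fixture
def epochs_factory():
    return make_epochs


@pytest.fixture
def sine_epochs():
    """Single-channel sinusoid factory: freq in Hz, n epochs, optional phase rng."""

    def _make(freq, n_epochs=4, sfreq=500.0, tmin=-1000.0, n_s=1000, amp=1.0,
              phase_rng=None):
        t = (tmin + np.arange(n_s) / sfreq * 1000.0) / 1000.0
        if phase_rng is None:
            phases = np.zeros(n_epochs)
        else:
            phases = phase_rng.uniform(0, 2 * np.pi, n_epochs)
        data = amp * np.cos(2 * np.pi * freq * t[None, :] + phases[:, None])
        return make_epochs(data[:, None, :], sfreq=sfreq, tmin=tmin)

    return _make
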