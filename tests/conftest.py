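import numpy as np
import pytest

from ssvepsr.signal_model import (
    DEFAULT_CHANNELS,
    EEGEpoch,
    SyntheticConfig,
    generate_epoch,
    make_template_bank,
    stimulus_grid,
    time_axis,
)


@pytest.fixture(scope="session")
def stim_freqs():
    return stimulus_grid()


@pytest.fixture(scope="session")
def bank_2s(stim_freqs):
    """35-target template bank for 2 s epochs at 1 kHz, k=2 harmonics."""
    return make_template_bank(stim_freqs, k=2, fs=1000.0, n_samples=2000)


@pytest.fixture
def noiseless_epoch():
    """Factory: noiseless synthetic epoch at a given frequency."""

    def _make(f, duration=2.0, fs=1000.0, seed=0, **kw):
        cfg = SyntheticConfig(
            f_target=f, duration=duration, fs=fs, snr_db=float("inf"), seed=seed, **kw
        )
        return generate_epoch(cfg)

    return _make


@pytest.fixture
def rank1_epoch():
    """Factory: pure rank-1 sinusoidal epoch (fixed gains, no noise)."""

    def _make(f, duration=2.0, fs=1000.0, n_channels=8, harmonic_ratio=0.0, phase=0.3):
        n = int(round(duration * fs))
        t = time_axis(n, fs)
        wave = np.sin(2 * np.pi * f * t + phase)
        if harmonic_ratio:
            wave = wave + harmonic_ratio * np.sin(4 * np.pi * f * t + 0.7)
        gains = np.linspace(0.8, 1.2, n_channels)
        names = DEFAULT_CHANNELS[:n_channels] if n_channels <= 8 else tuple(
            f"CH{i}" for i in range(n_channels)
        )
        return EEGEpoch(np.outer(gains, wave), fs=fs, channel_names=names, true_freq=f)

    return _make
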