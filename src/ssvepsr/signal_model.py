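"""Domain containers and a seeded synthetic SSVEP generator.

The central object is :class:`EEGEpoch`, one stimulation trial of
multichannel occipital EEG.  :class:`TemplateBank` holds the sine/cosine
reference matrices ``Y_f`` used both by the canonical-correlation scorers
and by the spatial filter.  :func:`generate_epoch` produces synthetic
epochs that emulate a motion-checkerboard SSVEP recording: a weak nearly
harmonic-free sinusoidal response mixed across channels on top of a
1/f^alpha + white EEG-like background.

Conventions shared by every module in this package:

* ``data`` is ``(n_channels, n_samples)`` in microvolts;
* the discrete time axis starts at ``t = 1/fs`` (sample ``n`` sits at
  ``n/fs`` for ``n = 1..N``), matching the reference-template definition.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "EEGEpoch",
    "TemplateBank",
    "SyntheticConfig",
    "stimulus_grid",
    "time_axis",
    "make_template_bank",
    "generate_epoch",
    "generate_dataset",
    "save_epoch_npz",
    "load_epoch_npz",
    "save_epoch_csv",
    "load_epoch_csv",
    "load_epoch_edf",
]

#: Occipital/parieto-occipital montage used for SSVEP recordings.
DEFAULT_CHANNELS = ("POz", "PO3", "PO4", "PO5", "PO6", "Oz", "O1", "O2")


def stimulus_grid(low: float = 3.0, high: float = 20.0, step: float = 0.5) -> np.ndarray:
    """Candidate stimulus frequencies: ``low..high`` inclusive at ``step`` Hz.

    The default 3-20 Hz grid at 0.5 Hz spacing yields 35 targets.
    """
    n = int(round((high - low) / step)) + 1
    return low + step * np.arange(n)


def time_axis(n_samples: int, fs: float) -> np.ndarray:
    """Sample times ``1/fs, 2/fs, ..., n_samples/fs`` (seconds)."""
    return np.arange(1, n_samples + 1) / fs


@dataclass(frozen=True)
class EEGEpoch:
    """One trial of multichannel EEG.

    Parameters
    ----------
    data
        Array ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered channel labels, one per row of ``data``.
    true_freq
        Stimulus frequency in Hz when known (evaluation label), else None.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    true_freq: float | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got ndim={data.ndim}")
        if data.shape[0] < 1 or data.shape[1] < 2:
            raise ValueError(f"need >=1 channel and >=2 samples, got shape {data.shape}")
        if not np.isfinite(data).all():
            raise ValueError("epoch data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        names = tuple(self.channel_names)
        if len(names) != data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[0]} channels"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the sample vector of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[idx]

    def crop(self, duration: float) -> "EEGEpoch":
        """First ``duration`` seconds of the epoch (stimulus-onset aligned)."""
        n = int(round(duration * self.fs))
        if n > self.n_samples:
            raise ValueError(
                f"requested {duration} s but epoch holds {self.duration} s"
            )
        if n < 2:
            raise ValueError("cropped epoch would be shorter than 2 samples")
        return replace(self, data=self.data[:, :n])


@dataclass(frozen=True)
class TemplateBank:
    """Sine/cosine reference matrices per candidate frequency.

    ``templates[f]`` is ``(2k, n_samples)`` with rows
    ``cos(2*pi*j*f*t), sin(2*pi*j*f*t)`` for harmonics ``j = 1..k`` and
    ``t = 1/fs .. n_samples/fs``.
    """

    freqs: tuple[float, ...]
    k: int
    fs: float
    n_samples: int
    templates: Mapping[float, np.ndarray]

    def __getitem__(self, f: float) -> np.ndarray:
        try:
            return self.templates[float(f)]
        except KeyError:
            raise KeyError(f"frequency {f} Hz not in bank") from None

    def __contains__(self, f: float) -> bool:
        return float(f) in self.templates

    def __len__(self) -> int:
        return len(self.freqs)


def make_template_bank(
    freqs: Sequence[float], k: int, fs: float, n_samples: int
) -> TemplateBank:
    """Build reference templates ``Y_f`` for each candidate frequency.

    Raises if any harmonic ``k*f`` reaches the Nyquist frequency, if the
    frequency list is empty, or if frequencies repeat.
    """
    freqs = [float(f) for f in freqs]
    if not freqs:
        raise ValueError("empty candidate frequency list")
    if len(set(freqs)) != len(freqs):
        raise ValueError("candidate frequencies must be unique")
    if k < 1:
        raise ValueError(f"harmonic count must be >=1, got {k}")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    nyquist = fs / 2.0
    bad = [f for f in freqs if f <= 0 or k * f >= nyquist]
    if bad:
        raise ValueError(
            f"frequencies {bad} invalid: need 0 < k*f < fs/2 = {nyquist} Hz"
        )
    t = time_axis(n_samples, fs)
    templates: dict[float, np.ndarray] = {}
    for f in sorted(freqs):
        rows = []
        for j in range(1, k + 1):
            w = 2.0 * math.pi * j * f * t
            rows.append(np.cos(w))
            rows.append(np.sin(w))
        templates[f] = np.vstack(rows)
    return TemplateBank(
        freqs=tuple(sorted(freqs)), k=k, fs=fs, n_samples=n_samples, templates=templates
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one simulated SSVEP epoch.

    The defaults emulate a 3 s motion-checkerboard trial recorded at
    1,000 Hz over 8 occipital channels: a sinusoidal response at the gazed
    frequency with a weak first harmonic (``harmonic_ratio`` of the
    fundamental amplitude), projected to the channels through a per-channel
    gain vector, buried in 1/f^alpha + white background noise at a
    per-channel SNR of ``snr_db``.

    ``snr_db = inf`` requests a noiseless epoch.  ``phase``/``harmonic_phase``
    of None draw seeded uniform phases; ``mixing`` of None draws an
    all-ones gain vector with seeded +/-20% jitter.
    """

    f_target: float
    duration: float = 3.0
    fs: float = 1000.0
    n_channels: int = 8
    channel_names: tuple[str, ...] | None = None
    amp_fundamental: float = 1.0
    harmonic_ratio: float = 0.1
    phase: float | None = None
    harmonic_phase: float | None = None
    mixing: tuple[float, ...] | None = None
    noise_alpha: float = 1.0
    white_fraction: float = 0.1
    snr_db: float = -16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.f_target <= 0 or self.f_target >= self.fs / 2:
            raise ValueError(
                f"f_target must lie in (0, fs/2), got {self.f_target} at fs={self.fs}"
            )
        if self.harmonic_ratio < 0:
            raise ValueError("harmonic_ratio must be >= 0")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.mixing is not None and len(self.mixing) != self.n_channels:
            raise ValueError(
                f"mixing has {len(self.mixing)} entries for {self.n_channels} channels"
            )
        if int(round(self.duration * self.fs)) < 2:
            raise ValueError("duration*fs must give at least 2 samples")


def _colored_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, alpha: float
) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum, unit-ish power."""
    white = rng.standard_normal((n_channels, n_samples))
    if alpha == 0:
        return white
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-alpha / 2.0)
    shaping[0] = 0.0  # no DC drift
    colored = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    # normalize to unit average power per channel
    rms = np.sqrt(np.mean(colored**2, axis=1, keepdims=True))
    return colored / rms


def generate_epoch(cfg: SyntheticConfig) -> EEGEpoch:
    """Simulate one labelled SSVEP epoch.

    The per-channel SSVEP-to-background power ratio equals ``cfg.snr_db``
    by construction (background rescaled channel-wise).  Identical config
    (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.fs))
    t = time_axis(n, cfg.fs)

    phase = rng.uniform(0, 2 * math.pi) if cfg.phase is None else cfg.phase
    phase2 = (
        rng.uniform(0, 2 * math.pi) if cfg.harmonic_phase is None else cfg.harmonic_phase
    )
    if cfg.mixing is None:
        mixing = 1.0 + 0.2 * rng.uniform(-1, 1, size=cfg.n_channels)
    else:
        mixing = np.asarray(cfg.mixing, dtype=float)

    wave = np.sin(2 * math.pi * cfg.f_target * t + phase)
    if cfg.harmonic_ratio > 0:
        wave = wave + cfg.harmonic_ratio * np.sin(
            4 * math.pi * cfg.f_target * t + phase2
        )
    signal = np.outer(mixing * cfg.amp_fundamental, wave)

    if math.isinf(cfg.snr_db):
        data = signal
    else:
        colored = _colored_noise(rng, cfg.n_channels, n, cfg.noise_alpha)
        white = rng.standard_normal((cfg.n_channels, n))
        white *= math.sqrt(cfg.white_fraction) / np.sqrt(
            np.mean(white**2, axis=1, keepdims=True)
        )
        background = colored + white
        bg_power = np.mean(background**2, axis=1)
        if np.any(bg_power == 0):
            raise ValueError("zero background power with finite snr_db requested")
        sig_power = np.mean(signal**2, axis=1)
        target_bg = sig_power / 10.0 ** (cfg.snr_db / 10.0)
        scale = np.sqrt(target_bg / bg_power)
        # signal-free channels keep unit-power background (no SNR defined)
        scale[sig_power == 0] = 1.0
        data = signal + scale[:, None] * background

    if cfg.channel_names is not None:
        names = tuple(cfg.channel_names)
    elif cfg.n_channels == len(DEFAULT_CHANNELS):
        names = DEFAULT_CHANNELS
    else:
        names = tuple(f"CH{i + 1}" for i in range(cfg.n_channels))
    return EEGEpoch(data=data, fs=cfg.fs, channel_names=names, true_freq=cfg.f_target)


def generate_dataset(
    freqs: Sequence[float],
    trials_per_freq: int,
    cfg_base: SyntheticConfig,
    seed: int,
) -> list[EEGEpoch]:
    """Labelled dataset: ``trials_per_freq`` epochs at each frequency.

    Per-epoch seeds are spawned deterministically from ``seed`` so the whole
    dataset is reproducible while epochs stay mutually independent.
    """
    if trials_per_freq < 1:
        raise ValueError("trials_per_freq must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(freqs) * trials_per_freq)
    epochs: list[EEGEpoch] = []
    i = 0
    for f in freqs:
        for _ in range(trials_per_freq):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            epochs.append(
                generate_epoch(replace(cfg_base, f_target=float(f), seed=child_seed))
            )
            i += 1
    return epochs


# ---------------------------------------------------------------------------
# Epoch I/O

def save_epoch_npz(path, epoch: EEGEpoch) -> None:
    np.savez(
        path,
        data=epoch.data,
        fs=epoch.fs,
        channel_names=np.array(epoch.channel_names),
        true_freq=np.nan if epoch.true_freq is None else epoch.true_freq,
    )


def load_epoch_npz(path) -> EEGEpoch:
    with np.load(path, allow_pickle=False) as z:
        tf = float(z["true_freq"])
        return EEGEpoch(
            data=z["data"],
            fs=float(z["fs"]),
            channel_names=tuple(str(c) for c in z["channel_names"]),
            true_freq=None if math.isnan(tf) else tf,
        )


def save_epoch_csv(path, epoch: EEGEpoch) -> None:
    """Long-format CSV: header comment with fs/true_freq, then
    channel,sample_index,value rows."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# fs={epoch.fs}\n")
        fh.write(f"# true_freq={'' if epoch.true_freq is None else epoch.true_freq}\n")
        w = csv.writer(fh)
        w.writerow(["channel", "sample_index", "value"])
        for name, row in zip(epoch.channel_names, epoch.data):
            for i, v in enumerate(row):
                w.writerow([name, i, repr(float(v))])


def load_epoch_csv(path) -> EEGEpoch:
    fs = None
    true_freq: float | None = None
    series: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "fs":
                    fs = float(val)
                elif key.strip() == "true_freq":
                    true_freq = float(val) if val else None
                continue
            break
        fh.seek(0)
        rows = (r for r in csv.reader(fh) if r and not r[0].startswith("#"))
        header = next(rows)
        if header[:3] != ["channel", "sample_index", "value"]:
            raise ValueError(f"unexpected CSV header {header}")
        for name, _, value in rows:
            if name not in series:
                series[name] = []
                order.append(name)
            series[name].append(float(value))
    if fs is None:
        raise ValueError("CSV missing '# fs=' header line")
    data = np.array([series[name] for name in order])
    return EEGEpoch(data=data, fs=fs, channel_names=tuple(order), true_freq=true_freq)


def load_epoch_edf(path, channels: Sequence[str] | None = None, true_freq: float | None = None) -> EEGEpoch:
    """Read one EDF recording as a single epoch (requires ``mne``)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF input requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGEpoch(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        true_freq=true_freq,
    )
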