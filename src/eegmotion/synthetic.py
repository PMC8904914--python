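"""Deterministic synthetic EEG corpora with class-conditional band structure.

The generator emulates the shape of a benchmark affective-EEG corpus —
40-channel trials sampled at 128 Hz, a few seconds long, one categorical
emotion label per trial — without any physiological forward modeling.
Class identity is encoded purely in the relative power of the five
canonical EEG rhythms (delta 1-4, theta 4-8, alpha 8-13, beta 13-30,
gamma 30-45 Hz): each class has a band-power profile, each channel of a
trial is a sum of band-limited sinusoids with random frequencies and
phases whose amplitudes realize that profile, plus 1/f "pink" background
noise and, optionally, sparse large single-sample impulses that the
median-filter stage is meant to remove.

Because every descriptor in the feature module is spectral or energetic,
encoding class structure in band power ensures the pipeline's features —
and not an accidental waveform shortcut — carry the class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DEFAULT_EMOTIONS, EEGRecording, LabelVocabulary, SignalDataset
from .exceptions import ConfigurationError

#: Canonical EEG rhythm bands, Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}
_BAND_ORDER = tuple(BANDS)


def default_band_profiles(n_classes: int, dominant_weight: float = 0.8) -> np.ndarray:
    """One normalized band-power profile per class, each dominated by a
    different rhythm (cycling through the five bands)."""
    if not 0 < dominant_weight < 1:
        raise ConfigurationError("dominant_weight must be in (0, 1)")
    profiles = np.full(
        (n_classes, len(_BAND_ORDER)),
        (1.0 - dominant_weight) / (len(_BAND_ORDER) - 1),
    )
    for k in range(n_classes):
        profiles[k, k % len(_BAND_ORDER)] = dominant_weight
    return profiles


@dataclass(frozen=True)
class SynthConfig:
    """Corpus-generation parameters.

    ``n_classes`` / ``trials_per_class`` define the balanced label layout;
    ``channels`` x (``fs`` * ``duration``) is each trial's amplitude matrix;
    ``band_profiles`` (n_classes x 5, rows sum to 1) sets per-class relative
    power over delta/theta/alpha/beta/gamma — defaults dominate a different
    band per class; ``pink_noise_level`` is the RMS of the 1/f background
    relative to the oscillatory RMS; ``impulse_rate`` (events/s/channel) and
    ``impulse_amplitude`` (microvolts) control artifact spikes;
    ``amplitude`` is the oscillatory RMS in microvolts.
    """

    n_classes: int = 4
    trials_per_class: int = 40
    channels: int = 40
    fs: float = 128.0
    duration: float = 4.0
    band_profiles: tuple = None
    pink_noise_level: float = 0.1
    impulse_rate: float = 0.0
    impulse_amplitude: float = 100.0
    amplitude: float = 10.0
    sines_per_band: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 1 or self.trials_per_class < 1 or self.channels < 1:
            raise ConfigurationError("counts must all be >= 1")
        max_edge = max(high for _, high in BANDS.values())
        if not self.fs > 2 * max_edge:
            raise ConfigurationError(
                f"fs must exceed twice the highest band edge ({2 * max_edge} Hz)"
            )
        if self.pink_noise_level < 0 or self.impulse_rate < 0:
            raise ConfigurationError("noise levels must be >= 0")
        profiles = (
            default_band_profiles(self.n_classes)
            if self.band_profiles is None
            else np.asarray(self.band_profiles, dtype=float)
        )
        if profiles.shape != (self.n_classes, len(_BAND_ORDER)):
            raise ConfigurationError(
                f"band_profiles must have shape ({self.n_classes}, {len(_BAND_ORDER)})"
            )
        if (profiles < 0).any() or (profiles.sum(axis=1) == 0).any():
            raise ConfigurationError(
                "band profiles must be non-negative with positive sums"
            )
        profiles = profiles / profiles.sum(axis=1, keepdims=True)
        object.__setattr__(
            self, "band_profiles", tuple(map(tuple, profiles))
        )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))

    def class_names(self) -> tuple[str, ...]:
        if self.n_classes <= len(DEFAULT_EMOTIONS):
            return DEFAULT_EMOTIONS[: self.n_classes]
        return tuple(f"class_{k}" for k in range(self.n_classes))


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white noise."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shaping = np.ones_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaping[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * shaping, n=n)
    return pink / np.sqrt(np.mean(pink**2))


def _trial_signal(cfg: SynthConfig, profile: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.n_samples) / cfg.fs
    signal = np.zeros((cfg.channels, cfg.n_samples))
    for c in range(cfg.channels):
        x = np.zeros(cfg.n_samples)
        for b, name in enumerate(_BAND_ORDER):
            if profile[b] == 0:
                continue
            low, high = BANDS[name]
            # Power proportional to the profile: per-sinusoid amplitude
            # a satisfies sum over sines of a^2/2 = profile_b.
            amp = np.sqrt(2.0 * profile[b] / cfg.sines_per_band)
            freqs = rng.uniform(low, high, size=cfg.sines_per_band)
            phases = rng.uniform(0, 2 * np.pi, size=cfg.sines_per_band)
            x += amp * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)
        if cfg.pink_noise_level > 0:
            x = x + cfg.pink_noise_level * _pink_noise(cfg.n_samples, rng)
        signal[c] = cfg.amplitude * x
    return signal


def inject_impulses(
    recording: EEGRecording,
    rate: float,
    amplitude: float,
    rng: np.random.Generator,
) -> EEGRecording:
    """Add isolated single-sample +/- ``amplitude`` spikes at Poisson times.

    ``rate`` is in events per second per channel; adjacent candidate
    positions are thinned so spikes stay isolated (which is what makes them
    removable by a width-3 median).  ``rate=0`` returns an identical copy.
    """
    if rate < 0:
        raise ConfigurationError("impulse rate must be >= 0")
    signal = recording.signal.copy()
    if rate > 0:
        n = recording.n_samples
        for c in range(recording.n_channels):
            k = rng.poisson(rate * recording.duration)
            if k == 0:
                continue
            positions = np.sort(rng.choice(n, size=min(k, n), replace=False))
            keep = np.ones(len(positions), dtype=bool)
            keep[1:] = np.diff(positions) > 1  # drop adjacent spikes
            positions = positions[keep]
            signs = rng.choice([-1.0, 1.0], size=len(positions))
            signal[c, positions] += signs * amplitude
    return recording.replace_signal(signal)


def generate_corpus(cfg: SynthConfig | None = None) -> SignalDataset:
    """Balanced labeled corpus; bitwise-deterministic given ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.class_names()
    vocabulary = LabelVocabulary(names)
    profiles = np.asarray(cfg.band_profiles)
    recordings = []
    for k, name in enumerate(names):
        for trial in range(cfg.trials_per_class):
            signal = _trial_signal(cfg, profiles[k], rng)
            rec = EEGRecording(
                signal=signal,
                fs=cfg.fs,
                label=name,
                meta={"class_index": k, "trial": trial, "synthetic": True},
            )
            if cfg.impulse_rate > 0:
                rec = inject_impulses(
                    rec, cfg.impulse_rate, cfg.impulse_amplitude, rng
                )
            recordings.append(rec)
    return SignalDataset(recordings=recordings, vocabulary=vocabulary)
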