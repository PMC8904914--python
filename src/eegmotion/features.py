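"""Hand-crafted EEG descriptors and feature-vector assembly.

Seven descriptor families are computed per recording and concatenated into
one flat feature vector with named, contiguous blocks:

``q1``  multi-level orthonormal Haar approximation of the channel-averaged
        signal, truncated/zero-padded to a fixed length (default 64);
``q2``  spectral flatness per (channel, frame) — geometric over arithmetic
        mean of spectral power, 1 for white spectra, 0 for tonal ones;
``q3``  natural-log band power per (channel, band);
``q4``  fluctuation index — mean absolute successive difference, averaged
        over channels (one scalar);
``q5``  spectral decrease per (channel, frame) — slope-like fall-off of the
        magnitude spectrum relative to its lowest non-DC bin;
``q6``  spectral roll-off frequency per (channel, frame);
``q7``  relative energy of one band of the channel-averaged signal (scalar).

Spectral conventions: one-sided DFT, rectangular window by default, power =
magnitude squared, DC bin excluded from flatness/decrease/roll-off.  With
the default layout (40 channels, 2 frames per channel, one band per
channel) the block lengths are 64/80/40/1/80/80/1 — 346 features in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .data import EEGRecording, SignalDataset
from .exceptions import (
    ConfigurationError,
    InputTooShortError,
    UndefinedInputError,
)

BLOCK_NAMES = ("q1", "q2", "q3", "q4", "q5", "q6", "q7")


@dataclass(frozen=True)
class SpectrumFrame:
    """One-sided magnitude spectrum of a signal segment."""

    magnitudes: np.ndarray  # |X_k| for k = 0..n//2, finite, >= 0
    bin_freqs: np.ndarray   # Hz, same length

    def __post_init__(self):
        mags = np.asarray(self.magnitudes, dtype=float)
        freqs = np.asarray(self.bin_freqs, dtype=float)
        object.__setattr__(self, "magnitudes", mags)
        object.__setattr__(self, "bin_freqs", freqs)
        if mags.shape != freqs.shape:
            raise ConfigurationError("magnitudes and bin_freqs must align")
        if not np.isfinite(mags).all() or (mags < 0).any():
            raise ConfigurationError("magnitudes must be finite and non-negative")

    @property
    def power(self) -> np.ndarray:
        return self.magnitudes**2


@dataclass(frozen=True)
class FeatureLayout:
    """Configuration that fixes every block length of the feature vector.

    ``dwt_len``             length of the Haar approximation block (q1);
    ``frames_per_channel``  contiguous frames each channel is cut into for
                            the framed spectral descriptors (q2, q5, q6);
    ``logbp_bands``         (low, high) Hz bands for q3, one value per
                            (channel, band);
    ``rolloff_fraction``    energy fraction for the roll-off frequency;
    ``relative_band``       (low, high) Hz band for the q7 energy ratio
                            (default 8-13 Hz, the alpha band);
    ``window_fn``           taper for the framed spectra.
    """

    dwt_len: int = 64
    frames_per_channel: int = 2
    logbp_bands: tuple[tuple[float, float], ...] = ((0.5, 45.0),)
    rolloff_fraction: float = 0.85
    relative_band: tuple[float, float] = (8.0, 13.0)
    window_fn: str = "rectangular"

    def __post_init__(self):
        if self.dwt_len < 1:
            raise ConfigurationError("dwt_len must be >= 1")
        if self.frames_per_channel < 1:
            raise ConfigurationError("frames_per_channel must be >= 1")
        if not 0 < self.rolloff_fraction <= 1:
            raise ConfigurationError("rolloff_fraction must be in (0, 1]")
        if self.window_fn not in ("rectangular", "hann"):
            raise ConfigurationError(f"unknown window_fn {self.window_fn!r}")
        bands = tuple(tuple(map(float, b)) for b in self.logbp_bands)
        object.__setattr__(self, "logbp_bands", bands)
        object.__setattr__(
            self, "relative_band", tuple(map(float, self.relative_band))
        )
        for low, high in bands + (self.relative_band,):
            if not 0 <= low < high:
                raise ConfigurationError(f"invalid band ({low}, {high})")

    def block_sizes(self, n_channels: int) -> dict[str, int]:
        per_frame = n_channels * self.frames_per_channel
        return {
            "q1": self.dwt_len,
            "q2": per_frame,
            "q3": n_channels * len(self.logbp_bands),
            "q4": 1,
            "q5": per_frame,
            "q6": per_frame,
            "q7": 1,
        }

    def spans(self, n_channels: int) -> dict[str, slice]:
        sizes = self.block_sizes(n_channels)
        spans, start = {}, 0
        for name in BLOCK_NAMES:
            spans[name] = slice(start, start + sizes[name])
            start += sizes[name]
        return spans

    def total_length(self, n_channels: int) -> int:
        return sum(self.block_sizes(n_channels).values())


@dataclass
class FeatureVector:
    """Flat descriptor vector with named block spans (q1..q7)."""

    values: np.ndarray
    spans: dict[str, slice]

    def block(self, name: str) -> np.ndarray:
        return self.values[self.spans[name]]


@dataclass
class FeatureMatrix:
    """Stack of feature vectors: rows = recordings (and augmented copies).

    ``groups[i]`` is the index of the source recording of row ``i`` so that
    evaluation splits can keep a recording and its noisy copies together.
    """

    X: np.ndarray
    labels: np.ndarray
    layout: FeatureLayout
    spans: dict[str, slice]
    groups: np.ndarray = None
    label_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.groups is None:
            self.groups = np.arange(self.X.shape[0])
        self.groups = np.asarray(self.groups, dtype=int)
        if not (len(self.X) == len(self.labels) == len(self.groups)):
            raise ConfigurationError("X, labels and groups must have equal length")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def column_names(self) -> list[str]:
        names = []
        for block in BLOCK_NAMES:
            span = self.spans[block]
            names.extend(f"{block}:{i}" for i in range(span.stop - span.start))
        return names


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def frame_signal(channel: np.ndarray, n_frames: int) -> list[np.ndarray]:
    """Cut a 1-D signal into ``n_frames`` equal contiguous segments.

    The trailing remainder of ``len(channel) % n_frames`` samples is dropped.
    """
    channel = np.asarray(channel, dtype=float)
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    seg = len(channel) // n_frames
    if seg < 2:
        raise InputTooShortError(
            f"signal of length {len(channel)} too short for {n_frames} frames"
        )
    return [channel[i * seg:(i + 1) * seg] for i in range(n_frames)]


def magnitude_spectrum(
    segment: np.ndarray, fs: float, window_fn: str = "rectangular"
) -> SpectrumFrame:
    """One-sided DFT magnitude spectrum of a segment (bins 0..n//2)."""
    segment = np.asarray(segment, dtype=float)
    n = len(segment)
    if n < 2:
        raise InputTooShortError("segment must have at least 2 samples")
    if window_fn == "hann":
        segment = segment * np.hanning(n)
    elif window_fn != "rectangular":
        raise ConfigurationError(f"unknown window_fn {window_fn!r}")
    mags = np.abs(np.fft.rfft(segment))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumFrame(magnitudes=mags, bin_freqs=freqs)


def haar_dwt(signal: np.ndarray, level: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Multi-level orthonormal Haar decomposition.

    Returns ``(approximation, [detail_level_L, ..., detail_level_1])`` using
    the convention that the level-1 detail of a pair ``(a, b)`` is
    ``(a - b) / sqrt(2)``.  Energy is conserved when the signal length is a
    multiple of ``2**level``.
    """
    coeffs = pywt.wavedec(
        np.asarray(signal, dtype=float), "haar", mode="periodization", level=level
    )
    return coeffs[0], coeffs[1:]


def dwt_block(recording: EEGRecording, layout: FeatureLayout) -> np.ndarray:
    """Haar approximation of the channel-averaged signal, fixed length ``dwt_len``.

    The decomposition level is the smallest L >= 1 whose approximation is no
    longer than ``dwt_len``; the result is truncated or zero-padded to
    exactly ``dwt_len`` values.
    """
    avg = recording.signal.mean(axis=0)
    n = len(avg)
    if n < layout.dwt_len:
        raise InputTooShortError(
            f"signal length {n} shorter than dwt_len {layout.dwt_len}"
        )
    level = 1
    while int(np.ceil(n / 2**level)) > layout.dwt_len:
        level += 1
    approx, _ = haar_dwt(avg, level)
    out = np.zeros(layout.dwt_len)
    m = min(len(approx), layout.dwt_len)
    out[:m] = approx[:m]
    return out


def spectral_flatness(frame: SpectrumFrame) -> float:
    """Geometric / arithmetic mean of spectral power (DC excluded), in [0, 1]."""
    p = frame.power[1:]
    if len(p) == 0 or not p.any():
        raise UndefinedInputError("spectral flatness undefined for zero spectrum")
    am = p.mean()
    if (p == 0).any():
        return 0.0
    gm = np.exp(np.mean(np.log(p)))
    return float(min(gm / am, 1.0))


def log_band_power(
    channel: np.ndarray, band: tuple[float, float], fs: float
) -> float:
    """Natural log of summed one-sided spectral power within ``band`` (Hz)."""
    low, high = band
    if not 0 <= low < high <= fs / 2:
        raise ConfigurationError(f"band ({low}, {high}) outside [0, {fs / 2}] Hz")
    spec = magnitude_spectrum(channel, fs)
    mask = (spec.bin_freqs >= low) & (spec.bin_freqs <= high)
    power = float(spec.power[mask].sum())
    if power <= 0:
        raise UndefinedInputError(
            f"zero power in band ({low}, {high}) Hz over {mask.sum()} bins"
        )
    return float(np.log(power))


def fluctuation_index(recording: EEGRecording) -> float:
    """Mean absolute successive difference, averaged across channels.

    Per channel with N samples the index is
    ``(1/N) * sum_{z=1}^{N-1} |y(z+1) - y(z)|`` — a roughness measure that
    is 0 for constant signals and scales linearly with amplitude.
    """
    diffs = np.abs(np.diff(recording.signal, axis=1)).sum(axis=1)
    per_channel = diffs / recording.n_samples
    return float(per_channel.mean())


def spectral_decrease(frame: SpectrumFrame) -> float:
    """Slope-like spectral fall-off relative to the first non-DC bin.

    ``sum_{r=2}^{K} (s(r) - s(1)) / (r - 1)  /  sum_{r=2}^{K} s(r)`` over
    the non-DC magnitudes ``s``; negative when the spectrum decreases.
    """
    s = frame.magnitudes[1:]
    if len(s) < 2:
        raise UndefinedInputError("spectral decrease needs >= 2 non-DC bins")
    denom = s[1:].sum()
    if denom == 0:
        raise UndefinedInputError("spectral decrease undefined: zero denominator")
    ranks = np.arange(1, len(s))
    num = ((s[1:] - s[0]) / ranks).sum()
    return float(num / denom)


def spectral_rolloff(frame: SpectrumFrame, fraction: float = 0.85) -> float:
    """Lowest frequency below which ``fraction`` of the spectral energy lies.

    Computed over non-DC power bins; returns the frequency (Hz) of the first
    bin whose cumulative power reaches ``fraction`` of the total.
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    p = frame.power[1:]
    total = p.sum()
    if total <= 0:
        raise UndefinedInputError("spectral roll-off undefined for zero spectrum")
    cum = np.cumsum(p)
    # Tiny relative slack so fraction=1.0 hits the last nonzero bin despite
    # floating-point rounding in the cumulative sum.
    k = int(np.searchsorted(cum, fraction * total * (1 - 1e-12)))
    return float(frame.bin_freqs[1 + k])


def relative_energy(
    recording: EEGRecording, band: tuple[float, float] | None = None, fs: float | None = None
) -> float:
    """In-band fraction of total spectral power of the channel-averaged signal."""
    band = band if band is not None else (8.0, 13.0)
    fs = fs if fs is not None else recording.fs
    avg = recording.signal.mean(axis=0)
    spec = magnitude_spectrum(avg, fs)
    total = spec.power.sum()
    if total <= 0:
        raise UndefinedInputError("relative energy undefined for zero signal")
    low, high = band
    mask = (spec.bin_freqs >= low) & (spec.bin_freqs <= high)
    return float(spec.power[mask].sum() / total)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _framed_spectra(
    recording: EEGRecording, layout: FeatureLayout
) -> list[SpectrumFrame]:
    """Per (channel, frame) spectra, channel-major then frame order."""
    spectra = []
    for channel in recording.signal:
        for seg in frame_signal(channel, layout.frames_per_channel):
            spectra.append(magnitude_spectrum(seg, recording.fs, layout.window_fn))
    return spectra


def extract_feature_vector(
    recording: EEGRecording, layout: FeatureLayout | None = None
) -> FeatureVector:
    """Compute all seven blocks for one recording and concatenate them."""
    layout = layout or FeatureLayout()
    spans = layout.spans(recording.n_channels)
    values = np.empty(layout.total_length(recording.n_channels))

    def _compute(block: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"block {block}: {exc}") from exc

    values[spans["q1"]] = _compute("q1", lambda: dwt_block(recording, layout))
    spectra = _framed_spectra(recording, layout)
    values[spans["q2"]] = _compute(
        "q2", lambda: [spectral_flatness(f) for f in spectra]
    )
    values[spans["q3"]] = _compute(
        "q3",
        lambda: [
            log_band_power(channel, band, recording.fs)
            for channel in recording.signal
            for band in layout.logbp_bands
        ],
    )
    values[spans["q4"]] = _compute("q4", lambda: fluctuation_index(recording))
    values[spans["q5"]] = _compute(
        "q5", lambda: [spectral_decrease(f) for f in spectra]
    )
    values[spans["q6"]] = _compute(
        "q6", lambda: [spectral_rolloff(f, layout.rolloff_fraction) for f in spectra]
    )
    values[spans["q7"]] = _compute(
        "q7", lambda: relative_energy(recording, layout.relative_band)
    )
    return FeatureVector(values=values, spans=spans)


def extract_feature_matrix(
    dataset: SignalDataset, layout: FeatureLayout | None = None
) -> FeatureMatrix:
    """Feature vectors for every recording of a dataset, stacked row-wise."""
    layout = layout or FeatureLayout()
    if len(dataset) == 0:
        raise ConfigurationError("cannot extract features from an empty dataset")
    rows, labels = [], []
    spans = None
    for rec in dataset:
        fv = extract_feature_vector(rec, layout)
        if spans is None:
            spans = fv.spans
        rows.append(fv.values)
        labels.append(
            dataset.vocabulary.index(rec.label) if rec.label is not None else -1
        )
    return FeatureMatrix(
        X=np.vstack(rows),
        labels=np.asarray(labels),
        layout=layout,
        spans=spans,
        label_names=tuple(dataset.vocabulary),
    )


class FeatureExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping a list of recordings to the stacked feature matrix.

    Parameters mirror :class:`FeatureLayout`; the fitted ``spans_`` attribute
    exposes the block ranges of the output columns.
    """

    def __init__(
        self,
        dwt_len: int = 64,
        frames_per_channel: int = 2,
        logbp_bands: tuple = ((0.5, 45.0),),
        rolloff_fraction: float = 0.85,
        relative_band: tuple = (8.0, 13.0),
        window_fn: str = "rectangular",
    ):
        self.dwt_len = dwt_len
        self.frames_per_channel = frames_per_channel
        self.logbp_bands = logbp_bands
        self.rolloff_fraction = rolloff_fraction
        self.relative_band = relative_band
        self.window_fn = window_fn

    def _layout(self) -> FeatureLayout:
        return FeatureLayout(
            dwt_len=self.dwt_len,
            frames_per_channel=self.frames_per_channel,
            logbp_bands=tuple(tuple(b) for b in self.logbp_bands),
            rolloff_fraction=self.rolloff_fraction,
            relative_band=tuple(self.relative_band),
            window_fn=self.window_fn,
        )

    def fit(self, X, y=None):
        layout = self._layout()
        if len(X) > 0:
            self.spans_ = layout.spans(X[0].n_channels)
            self.n_features_out_ = layout.total_length(X[0].n_channels)
        return self

    def transform(self, X):
        layout = self._layout()
        rows = [extract_feature_vector(rec, layout).values for rec in X]
        return np.vstack(rows)
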