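"""Domain types and on-disk corpus I/O.

A corpus lives in a directory holding one headerless CSV per recording
(rows = channels, columns = samples) plus a JSON manifest that records the
sampling rate, the label vocabulary and, per recording, the file name,
label, channel names and free-form metadata.  The layout is deliberately
plain text so corpora diff cleanly and can be produced by any tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .exceptions import ConfigurationError, ParseError, VocabularyError

MANIFEST_NAME = "manifest.json"
MANIFEST_VERSION = 1

#: The sixteen discrete emotion classes recognised by default, in canonical
#: order.  Vocabulary order defines the integer encoding of labels, so this
#: tuple must never be reordered.
DEFAULT_EMOTIONS: tuple[str, ...] = (
    "pride", "elation", "joy", "satisfaction", "relief", "hope",
    "interest", "surprise", "sadness", "fear", "shame", "guilt",
    "envy", "disgust", "contempt", "anger",
)


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered set of class names; position defines the integer class index."""

    names: tuple[str, ...] = DEFAULT_EMOTIONS

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(names) == 0:
            raise ConfigurationError("vocabulary must contain at least one name")
        if any(not n for n in names):
            raise ConfigurationError("vocabulary names must be non-empty strings")
        if len(set(names)) != len(names):
            raise ConfigurationError("vocabulary names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise VocabularyError(
                f"label {name!r} not in vocabulary {list(self.names)}"
            ) from None


@dataclass
class EEGRecording:
    """One multichannel trial.

    Parameters
    ----------
    signal
        Amplitude matrix in microvolts, shape ``(channels, samples)``.
    fs
        Sampling rate in Hz.
    channel_names
        One name per channel; generated as ``ch00..`` when omitted.
    label
        Emotion-class name, or ``None`` for unlabeled data.
    meta
        Free-form provenance (subject / trial identifiers and the like).
    """

    signal: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ()
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ConfigurationError(
                f"signal must be 2-D (channels x samples), got shape {self.signal.shape}"
            )
        c, n = self.signal.shape
        if c < 1 or n < 2:
            raise ConfigurationError(
                f"signal needs >=1 channel and >=2 samples, got {c}x{n}"
            )
        if not np.isfinite(self.signal).all():
            raise ConfigurationError("signal contains non-finite amplitudes")
        if not self.fs > 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i:02d}" for i in range(c))
        else:
            self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != c:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def replace_signal(self, signal: np.ndarray, **meta_updates) -> "EEGRecording":
        """Copy of this recording with a new amplitude matrix, same metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EEGRecording(
            signal=signal,
            fs=self.fs,
            channel_names=self.channel_names,
            label=self.label,
            meta=meta,
        )


@dataclass
class SignalDataset:
    """Ordered collection of recordings plus the label vocabulary."""

    recordings: list[EEGRecording]
    vocabulary: LabelVocabulary = field(default_factory=LabelVocabulary)

    def __post_init__(self) -> None:
        for rec in self.recordings:
            if rec.label is not None:
                self.vocabulary.index(rec.label)  # raises VocabularyError

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterator[EEGRecording]:
        return iter(self.recordings)

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)

    def label_indices(self) -> np.ndarray:
        """Integer class index per labeled recording (vocabulary order)."""
        idx = [
            self.vocabulary.index(rec.label)
            for rec in self.recordings
            if rec.label is not None
        ]
        return np.asarray(idx, dtype=int)

    def label_counts(self) -> dict[str, int]:
        counts = {name: 0 for name in self.vocabulary}
        for rec in self.recordings:
            if rec.label is not None:
                counts[rec.label] += 1
        return counts


def _load_signal_csv(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    try:
        matrix = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError:
        # Re-parse slowly to report the offending cell.
        with open(path, "r", encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                for j, cell in enumerate(line.rstrip("\n").split(",")):
                    try:
                        float(cell)
                    except ValueError:
                        raise ParseError(
                            f"{path}: non-numeric cell {cell!r} at row {i}, column {j}"
                        ) from None
        raise ParseError(f"{path}: malformed CSV") from None
    return matrix


def write_dataset(dataset: SignalDataset, directory: str | Path) -> Path:
    """Write ``dataset`` as per-recording CSVs plus a JSON manifest.

    Returns the manifest path.  ``read_dataset`` inverts this to 12
    significant digits of amplitude.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fs_values = {rec.fs for rec in dataset.recordings}
    if len(fs_values) > 1:
        raise ConfigurationError(
            f"manifest stores a single sampling rate; dataset has {sorted(fs_values)}"
        )
    fs = fs_values.pop() if fs_values else None
    entries = []
    for i, rec in enumerate(dataset.recordings):
        fname = f"rec_{i:05d}.csv"
        np.savetxt(directory / fname, rec.signal, delimiter=",", fmt="%.12g")
        entries.append(
            {
                "file": fname,
                "label": rec.label,
                "channels": list(rec.channel_names),
                "meta": rec.meta,
            }
        )
    manifest = {
        "version": MANIFEST_VERSION,
        "fs": fs,
        "vocabulary": list(dataset.vocabulary),
        "recordings": entries,
    }
    manifest_path = directory / MANIFEST_NAME
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path


def read_dataset(manifest_path: str | Path) -> SignalDataset:
    """Load a corpus from its JSON manifest (inverse of :func:`write_dataset`)."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    vocabulary = LabelVocabulary(tuple(manifest["vocabulary"]))
    base = manifest_path.parent
    recordings = []
    for entry in manifest["recordings"]:
        signal = _load_signal_csv(base / entry["file"])
        label = entry.get("label")
        if label is not None:
            vocabulary.index(label)
        recordings.append(
            EEGRecording(
                signal=signal,
                fs=manifest["fs"],
                channel_names=tuple(entry.get("channels") or ()),
                label=label,
                meta=entry.get("meta") or {},
            )
        )
    return SignalDataset(recordings=recordings, vocabulary=vocabulary)
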