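"""Corpus augmentation by additive white Gaussian noise at the signal level.

Noise is added to the raw (or preprocessed) amplitude matrices — not to the
feature vectors — and features are re-extracted from the noisy copies, so a
copy's descriptors move coherently the way a genuinely noisier trial's
would.  Noise strength is set per channel through a signal-to-noise ratio
in dB, which makes the corruption invariant to amplitude units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EEGRecording, SignalDataset
from .exceptions import ConfigurationError, DegenerateInputError
from .features import FeatureLayout, FeatureMatrix, extract_feature_matrix


@dataclass(frozen=True)
class AugmentConfig:
    """snr_db: per-channel SNR of the injected noise; copies: noisy copies per trial."""

    snr_db: float = 20.0
    copies: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.copies < 0:
            raise ConfigurationError("copies must be >= 0")
        if not np.isfinite(self.snr_db):
            raise ConfigurationError("snr_db must be finite")


def add_awgn(
    recording: EEGRecording, snr_db: float, rng: np.random.Generator
) -> EEGRecording:
    """Return a copy of ``recording`` with iid Gaussian noise on every channel.

    The noise standard deviation per channel is ``RMS(channel) / 10**(snr_db/20)``,
    so every channel is corrupted at the same SNR regardless of its gain.
    """
    rms = np.sqrt(np.mean(recording.signal**2, axis=1))
    if (rms == 0).any():
        dead = [recording.channel_names[i] for i in np.flatnonzero(rms == 0)]
        raise DegenerateInputError(f"zero-RMS channel(s) {dead}: SNR undefined")
    sigma = rms / 10 ** (snr_db / 20.0)
    noise = rng.normal(0.0, 1.0, size=recording.signal.shape) * sigma[:, None]
    return recording.replace_signal(recording.signal + noise, augmented=True)


def augment_dataset(
    dataset: SignalDataset,
    layout: FeatureLayout | None = None,
    config: AugmentConfig | None = None,
) -> FeatureMatrix:
    """Extract features for the corpus plus ``copies`` noisy copies per trial.

    Rows 0..n-1 are the originals in corpus order, followed by one full
    corpus-ordered block per noisy copy; labels are duplicated onto copies
    and ``groups`` ties every copy back to its source row so evaluation
    splits can avoid leakage.  ``copies=0`` reduces to plain extraction.
    """
    if len(dataset) == 0:
        raise ConfigurationError("cannot augment an empty dataset")
    layout = layout or FeatureLayout()
    config = config or AugmentConfig()
    base = extract_feature_matrix(dataset, layout)
    if config.copies == 0:
        return base
    rng = np.random.default_rng(config.seed)
    n = len(dataset)
    blocks = [base.X]
    labels = [base.labels]
    groups = [np.arange(n)]
    for copy_idx in range(config.copies):
        rows = []
        for i, rec in enumerate(dataset):
            try:
                noisy = add_awgn(rec, config.snr_db, rng)
                rows.append(_extract_row(noisy, layout))
            except Exception as exc:
                raise type(exc)(
                    f"recording {i}, copy {copy_idx}: {exc}"
                ) from exc
        blocks.append(np.vstack(rows))
        labels.append(base.labels)
        groups.append(np.arange(n))
    return FeatureMatrix(
        X=np.vstack(blocks),
        labels=np.concatenate(labels),
        layout=layout,
        spans=base.spans,
        groups=np.concatenate(groups),
        label_names=base.label_names,
    )


def _extract_row(recording: EEGRecording, layout: FeatureLayout) -> np.ndarray:
    from .features import extract_feature_vector

    return extract_feature_vector(recording, layout).values
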