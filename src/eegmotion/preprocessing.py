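"""Noise removal: per-channel sliding-window median filtering.

The running median suppresses isolated large-amplitude artifacts (electrode
pops, movement spikes) without smearing oscillatory EEG morphology the way
a linear smoother would.  Channels are filtered independently — the filter
never mixes information across electrodes.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator, TransformerMixin
from scipy.ndimage import median_filter as _nd_median

from .data import EEGRecording
from .exceptions import ConfigurationError

_EDGE_MODES = {"replicate": "nearest", "reflect": "reflect"}


def median_filter(
    recording: EEGRecording, window: int = 3, edge_mode: str = "replicate"
) -> EEGRecording:
    """Apply a centred running median of length ``window`` to every channel.

    Parameters
    ----------
    recording
        Input trial; unchanged by the call.
    window
        Odd neighbourhood length in samples.  ``window=1`` is the identity.
    edge_mode
        ``"replicate"`` repeats the edge sample into the padding,
        ``"reflect"`` mirrors the signal about the edge.

    Returns
    -------
    EEGRecording
        Filtered copy; shape, sampling rate and label are preserved, and
        each output sample lies within [min, max] of its padded window.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"median window must be an odd integer >= 1, got {window}")
    if window > recording.n_samples:
        raise ConfigurationError(
            f"median window {window} exceeds signal length {recording.n_samples}"
        )
    if edge_mode not in _EDGE_MODES:
        raise ConfigurationError(
            f"edge_mode must be one of {sorted(_EDGE_MODES)}, got {edge_mode!r}"
        )
    if window == 1:
        return recording.replace_signal(recording.signal.copy())
    filtered = _nd_median(
        recording.signal, size=(1, window), mode=_EDGE_MODES[edge_mode]
    )
    return recording.replace_signal(filtered)


class MedianFilter(TransformerMixin, BaseEstimator):
    """Stateless transformer applying :func:`median_filter` to each recording.

    Operates on a list of :class:`~eegmotion.data.EEGRecording`, so it slots
    in ahead of :class:`~eegmotion.features.FeatureExtractor` in a pipeline.
    """

    def __init__(self, window: int = 3, edge_mode: str = "replicate"):
        self.window = window
        self.edge_mode = edge_mode

    def fit(self, X, y=None):
        # Nothing to learn; validate eagerly so misconfiguration fails here.
        if self.window < 1 or self.window % 2 == 0:
            raise ConfigurationError(
                f"median window must be an odd integer >= 1, got {self.window}"
            )
        return self

    def transform(self, X):
        return [median_filter(rec, self.window, self.edge_mode) for rec in X]
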