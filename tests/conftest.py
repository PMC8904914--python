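import numpy as np
import pytest

from eegmotion.data import EEGRecording
from eegmotion.synthetic import SynthConfig, generate_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def recording40():
    """One default-shaped trial: 40 channels, 128 Hz, 4 s."""
    corpus = generate_corpus(SynthConfig(n_classes=1, trials_per_class=1, seed=3))
    return corpus.recordings[0]


@pytest.fixture(scope="session")
def small_corpus():
    """Tiny two-class corpus for fast dataset-level tests."""
    return generate_corpus(
        SynthConfig(
            n_classes=2, trials_per_class=5, channels=6, duration=1.0, seed=11
        )
    )


@pytest.fixture
def toy_recording():
    signal = np.array([[0.0, 1.0, 0.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
    return EEGRecording(signal=signal, fs=4.0, label=None)
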