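import numpy as np
import pytest

from anesrecov.eeg_preprocess import STANDARD_21, EEGRecording, StateEpoch


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def make_epoch():
    """Factory for 21-channel state epochs from a channels x samples matrix."""

    def _make(data, fs=250.0, state="EC1", subject="S01"):
        data = np.atleast_2d(np.asarray(data, dtype=float))
        labels = list(STANDARD_21)[: data.shape[0]]
        return StateEpoch(subject, state, data, fs, labels)

    return _make


@pytest.fixture
def make_recording():
    """Factory for a recording carrying the 21 scalp channels + mastoids."""

    def _make(data, fs=250.0, subject="S01", mask=None):
        data = np.asarray(data, dtype=float)
        labels = (list(STANDARD_21) + ["M1", "M2"])[: data.shape[0]]
        return EEGRecording(subject, data, fs, labels, mask)

    return _make
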