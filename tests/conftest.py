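import numpy as np
import pytest

from lfpnet.preprocess import (
    Recording,
    bandpass,
    reject_artifacts,
    remove_line_noise,
    segment_epochs,
)
from lfpnet.synthgen import LfpGroundTruth, generate_recording

RATE = 512.0


def make_recording(data, motion=None, labels=None, rate=RATE):
    """Wrap raw channel arrays into a Recording with constant-active motion."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if motion is None:
        motion = np.ones(data.shape[1])
    if labels is None:
        labels = [f"CH{i}" for i in range(data.shape[0])]
    return Recording(data, rate, {lb: i for i, lb in enumerate(labels)}, motion)


@pytest.fixture(scope="session")
def wake_recording():
    """A 60-s synthetic wake recording with the default ground truth."""
    return generate_recording(LfpGroundTruth(seed=7), 60.0)


@pytest.fixture(scope="session")
def preprocessed(wake_recording):
    """The wake recording after notch/band-limit/segmentation/rejection."""
    rec = bandpass(remove_line_noise(wake_recording), 1.0, 256.0)
    eps = reject_artifacts(rec, segment_epochs(rec))
    return rec, eps
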