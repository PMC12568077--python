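import numpy as np
import pytest

from shankgait.config import RunConfig
from shankgait.containers import ImuRecording, LabeledRecording, RecordingMeta
from shankgait import synthgait


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def meta() -> RecordingMeta:
    return RecordingMeta("S000", "proximal_shank", 100.0)


def make_recording(accel, gyro, rate=100.0, subject="S000", frame="shank"):
    accel = np.asarray(accel, dtype=float)
    n = len(accel)
    t = np.arange(n) / rate
    return ImuRecording(t, accel, np.asarray(gyro, dtype=float),
                        RecordingMeta(subject, "proximal_shank", rate), frame)


def make_labeled(labels, accel=None, gyro=None, rate=100.0):
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if accel is None:
        accel = np.tile([0.0, 0.0, 9.81], (n, 1))
    if gyro is None:
        gyro = np.zeros((n, 3))
    return LabeledRecording(make_recording(accel, gyro, rate), labels)


@pytest.fixture
def walking_60s():
    """One deterministic 60 s average-speed walking segment plus truth."""
    return synthgait.synth_walking(synthgait.AVERAGE_PROFILE, 60.0, seed=7)
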