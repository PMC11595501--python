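import numpy as np
import pytest

from topodecode import montage as mtg
from topodecode.topomap import FrameSchedule, TrialRecording


@pytest.fixture(scope="session")
def frontal_montage():
    return mtg.standard_1020_positions(mtg.frontal_subset())


@pytest.fixture(scope="session")
def frontal_montage2d(frontal_montage):
    return mtg.project_to_disk(frontal_montage)


@pytest.fixture
def schedule():
    return FrameSchedule()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_trial(rng, frontal_montage2d):
    """A paper-conformant 15-channel, 512-sample, 256 Hz trial."""
    return TrialRecording(
        data=rng.standard_normal((15, 512)),
        rate=256,
        label="hello",
        subject="S01",
        channel_names=frontal_montage2d.labels,
    )


def make_trial(data, labels, label="w", subject="S01", rate=256):
    return TrialRecording(
        data=data, rate=rate, label=label, subject=subject, channel_names=labels
    )
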