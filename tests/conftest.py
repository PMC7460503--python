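import numpy as np
import pytest

from gaitphase.preprocessing import WindowingSpec, build_examples
from gaitphase.synthetic import GaitProfile, synthesize_recording


@pytest.fixture(scope="session")
def default_profile():
    return GaitProfile(speed=1.0, seed=7)


@pytest.fixture(scope="session")
def short_recording(default_profile):
    """20 s of default-profile walking at 200 Hz."""
    return synthesize_recording(default_profile, 20.0, subject_id="s00")


@pytest.fixture(scope="session")
def noise_free_recording():
    return synthesize_recording(
        GaitProfile(speed=1.0, noise_sd=0.0, seed=3), 10.0, subject_id="clean"
    )


@pytest.fixture(scope="session")
def example_set(short_recording):
    return build_examples(short_recording, WindowingSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
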