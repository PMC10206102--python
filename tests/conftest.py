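import numpy as np
import pytest

from galofrec import FiberParams, ObjectSpec, generate_objects, sample_fiber_model
from galofrec.synthetic import transmit_stack


@pytest.fixture(scope="session")
def small_spec():
    return ObjectSpec(image_size=64, seed=7)


@pytest.fixture(scope="session")
def small_objects(small_spec):
    return generate_objects(small_spec, 40)


@pytest.fixture(scope="session")
def drifting_model():
    return sample_fiber_model(64, FiberParams(n_frames=60, drift_max=3), seed=17)


@pytest.fixture(scope="session")
def drifting_stack(small_objects, drifting_model):
    return transmit_stack(small_objects, drifting_model)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
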