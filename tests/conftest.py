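import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hopfall as hf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fall_recording():
    return hf.generate_activity("Fall", seed=1)


@pytest.fixture(scope="session")
def fall_template(fall_recording):
    bm = hf.binarize(hf.fuse_axes(fall_recording))
    return hf.extract_template(bm, class_label="Fall")


@pytest.fixture(scope="session")
def fall_weights(fall_template):
    return hf.train_hebb(fall_template, eta=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_bipolar(rng, n):
    return rng.choice([-1.0, 1.0], size=n)
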