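import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stagedisc as sd

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return sd.default_design()


@pytest.fixture(scope="session")
def signal_dataset():
    """One strongly activated 6-stage dataset with 20 voxels (8 informative)."""
    roi = sd.RoiSpec(name="sig", n_voxels=20, n_informative=8, effect_amplitude=1.5)
    return sd.simulate_dataset(sd.default_design(), [roi], seed=11)


@pytest.fixture(scope="session")
def noise_dataset():
    roi = sd.RoiSpec(name="nul", n_voxels=12)
    return sd.simulate_dataset(sd.default_design(), [roi], seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def labeled_xy(ts, labels):
    mask = labels.labeled_mask
    return ts.data[mask], labels.labels[mask]
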