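import dataclasses

import numpy as np
import pytest

from orgpet.config import RunConfig
from orgpet.pipeline import simulate_subject


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def motion_cohort_features(default_config):
    """Fifty noiseless moving-phantom subjects (15 mm motion, 35% duty).

    Returns a list of {'nonORG': features, 'ORG': features} dicts, shared by
    the directional-reproduction tests.
    """
    cfg = dataclasses.replace(default_config, noise_scale=0.0, seed=20190313)
    return [simulate_subject(cfg, s) for s in range(50)]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
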