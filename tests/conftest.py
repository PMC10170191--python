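import numpy as np
import pytest

import dimvision as dv
from dimvision import pipeline


@pytest.fixture(scope="session")
def config() -> dv.StudyConfig:
    return dv.StudyConfig()


@pytest.fixture(scope="session")
def study_logs(config):
    """One full synthetic study (48 detection + 40 discrimination sessions)."""
    return pipeline.simulate(config, 123)


@pytest.fixture(scope="session")
def threshold_frame(config, study_logs):
    return pipeline.estimate(study_logs, config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2023)
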