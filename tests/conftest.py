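import numpy as np
import pytest

from sizedist import experiment as ex
from sizedist import get_model
from sizedist.experiment import reference_theta


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_config():
    return ex.ScheduleConfig()


@pytest.fixture(scope="session")
def model7():
    return get_model(7)


@pytest.fixture(scope="session")
def theta7(default_config, model7):
    return reference_theta(model7, default_config)


@pytest.fixture(scope="session")
def dataset7(default_config, model7, theta7):
    """One synthetic model-7 experiment (schedule + responses), seed-fixed."""
    rng = np.random.default_rng(20240917)
    df, manifest = ex.simulate_experiment(
        default_config, {"model_id": 7, "theta": theta7}, rng
    )
    return df, manifest
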