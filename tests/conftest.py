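import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from hospflow.config import default_config
from hospflow.staffing import ResourceSchedule


@pytest.fixture(scope="session")
def base_config():
    """The bundled default model (dedicated counters, no new patients)."""
    return default_config()


@pytest.fixture
def tight_schedule():
    """One MR counter per type: enough to finish the day, slow enough to queue."""
    return ResourceSchedule.uniform(
        {"N": 6, "N2": 3, "M1": 1, "M2": 1, "M3": 1, "M4": 1}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
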