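import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20230834)


@pytest.fixture()
def cluster_params():
    """The observed fluorescence cluster statistics of the validated assay."""
    return {"neg": (1764.0, 135.0), "pos": (5418.0, 212.0)}
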