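import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from napscan.synthetic_data import load_study, simulate_study, write_study

settings.register_profile(
    "napscan",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("napscan")


@pytest.fixture(scope="session")
def study1():
    """The default synthetic study at seed 1."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def loaded1(study1, tmp_path_factory):
    """The seed-1 study round-tripped through the on-disk formats."""
    out = tmp_path_factory.mktemp("study1")
    write_study(study1, out)
    return load_study(out)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
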