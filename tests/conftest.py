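import copy

import pytest
from hypothesis import HealthCheck, settings

from cvdprev import load_parameters

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ps():
    """The packaged default parameter set (treat as read-only)."""
    return load_parameters("default")


@pytest.fixture()
def ps_copy(ps):
    """A mutable deep copy for tests that tweak parameters."""
    return copy.deepcopy(ps)
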