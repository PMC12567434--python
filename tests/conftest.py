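import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mubudget import mpz_budget  # noqa: E402


@pytest.fixture(scope="session")
def budget():
    """The packaged Metopimazine HPLC-UV assay budget."""
    return mpz_budget()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
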