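import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from oryzatools import gen_sd1_pair, sd1_anchored_deletion_config, sd1_cds_deletion_config


@pytest.fixture(scope="session")
def anchored_scenario():
    """Reference/derived pair with the 383-column block and one anchored base."""
    return gen_sd1_pair(sd1_anchored_deletion_config(seed=1))


@pytest.fixture(scope="session")
def cds_scenario():
    """Pair with the 363-column coding-frame block and 83-bp novel intron."""
    return gen_sd1_pair(sd1_cds_deletion_config(seed=1))
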