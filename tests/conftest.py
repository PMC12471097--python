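import pytest
from hypothesis import HealthCheck, settings

import ampdigest as ad

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    """The built-in 57-peptide reference panel."""
    return ad.load_reference_dataset()


@pytest.fixture(scope="session")
def gi():
    """Default gastrointestinal rule set (pepsin, trypsin, chymotrypsin)."""
    return ad.gi_rules()


@pytest.fixture(scope="session")
def fragment_map(panel, gi):
    """Di/tripeptides released from the panel under the default rules."""
    return ad.unique_fragments(panel, gi, (2, 3))
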