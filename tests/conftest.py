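import pytest
from hypothesis import HealthCheck, settings

from pedddi import load_validation_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def validation_records():
    """The packaged 25-case pediatric DDI validation table."""
    return load_validation_table()
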