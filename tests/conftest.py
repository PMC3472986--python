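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

from tagdge import generate_reference  # noqa: E402


@pytest.fixture(scope="session")
def reference():
    """Small shared reference: 200 genes, 100-600nt, with genome."""
    return generate_reference(200, (100, 600), seed=7)
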