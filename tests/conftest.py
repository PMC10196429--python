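import pytest
from hypothesis import HealthCheck, settings

from ptabias import default_scenarios

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def paper_scenarios():
    """The four packaged generate/scale fu pairs at n=5000."""
    return default_scenarios()


@pytest.fixture(scope="session")
def scenario_by_label(paper_scenarios):
    return {c.label: c for c in paper_scenarios}
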