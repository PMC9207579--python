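import pytest

from asbacklog import PopulationParams


@pytest.fixture(scope="session")
def params() -> PopulationParams:
    """The published NHS England severe-AS population parameters."""
    return PopulationParams()
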