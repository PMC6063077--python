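import pytest

from xylosim import IntegrationConfig, list_fixtures, load_fixture

SPECIES = list(list_fixtures())


@pytest.fixture(scope="session")
def fixtures():
    """All bundled species parameter sets, keyed by name."""
    return {name: load_fixture(name) for name in SPECIES}


@pytest.fixture(scope="session")
def larix(fixtures):
    return fixtures["Larix decidua"]


@pytest.fixture(scope="session")
def fast_cfg():
    """Coarse-but-accurate integration for tests that loop over rings."""
    return IntegrationConfig(dt=0.05)
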