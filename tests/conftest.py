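import pytest

from somakit.dnds import build_site_tables
from somakit.fixtures import make_fixture_resources
from somakit.genome import build_mini_genome


@pytest.fixture(scope="session")
def genome():
    return build_mini_genome()


@pytest.fixture(scope="session")
def fixtures(genome):
    return make_fixture_resources(genome, seed=0)


@pytest.fixture(scope="session")
def site_tables(genome):
    return build_site_tables(genome)
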