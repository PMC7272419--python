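import pytest

from gemreduce.fixtures import (FixtureSpec, default_fixture_suite,
                                make_leukemia_toy, make_thermo_toy,
                                make_toy_gem)
from gemreduce.workflow import reduce_model


@pytest.fixture(scope="session")
def planted():
    """Seed-1 planted toy: (gem, thermo, ground truth)."""
    return make_toy_gem(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def planted_deep():
    """Planted fixture with a 4-reaction, 2-alternative medium chain."""
    return make_toy_gem(FixtureSpec(seed=2, medium_chain_len=4,
                                    medium_alternatives=2))


@pytest.fixture(scope="session")
def thermo_toy():
    return make_thermo_toy()


@pytest.fixture(scope="session")
def leukemia_toy():
    return make_leukemia_toy()


@pytest.fixture(scope="session")
def fixture_suite():
    """The ten oracle-verified planted fixtures of the acceptance battery."""
    return [make_toy_gem(spec) for spec in default_fixture_suite(1, 10)]


@pytest.fixture(scope="session")
def suite_reductions(fixture_suite):
    """Full reduction outcome per suite fixture (computed once)."""
    return [(gem, thermo, truth,
             reduce_model(gem, thermo, truth.medium, truth.core_config))
            for gem, thermo, truth in fixture_suite]


@pytest.fixture(scope="session")
def planted_reduction(planted):
    gem, thermo, truth = planted
    return reduce_model(gem, thermo, truth.medium, truth.core_config)
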