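import pytest

from fbdrank import io as fio
from fbdrank.data import ethiopia_path
from fbdrank.hazard_registry import load_registry, scoping_screen


@pytest.fixture(scope="session")
def candidates():
    return load_registry(ethiopia_path("registry.csv"))


@pytest.fixture(scope="session")
def retained(candidates):
    kept, _ = scoping_screen(candidates)
    return kept


@pytest.fixture(scope="session")
def metrics_best():
    return fio.read_metrics_wide(ethiopia_path("burden_metrics.csv"))


@pytest.fixture(scope="session")
def group_rounds():
    return fio.read_rankings_csv(ethiopia_path("group_rankings.csv"))


@pytest.fixture(scope="session")
def plenary_votes():
    return fio.read_votes_csv(ethiopia_path("plenary_votes.csv"))


@pytest.fixture(scope="session")
def attributed_deaths_fixture():
    return fio.read_attributed_deaths_csv(
        ethiopia_path("attributed_deaths_synthetic.csv")
    )


@pytest.fixture(scope="session")
def chains_and_allocations():
    return fio.read_chains_yaml(ethiopia_path("chains.yaml"))
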