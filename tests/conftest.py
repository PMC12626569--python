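import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from faerspv.cohort import build_dataset
from faerspv.ingest import deduplicate, restrict_to_cases
from faerspv.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_cases=3000, seed=11)


@pytest.fixture(scope="session")
def small_quarter(small_config):
    """(tables, ground_truth) for a 3000-case synthetic quarter."""
    return generate(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_quarter):
    """The analysis dataset built from the small quarter via dedup."""
    tables, _ = small_quarter
    survivors, _ = deduplicate(tables.demo)
    restricted = restrict_to_cases(tables, survivors["PRIMARYID"])
    restricted.demo = survivors
    return build_dataset(
        restricted, small_config.pt_list(), small_config.drug_dictionary()
    )
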