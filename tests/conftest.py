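import pytest
from hypothesis import HealthCheck, settings

from lncnet.synthetic import SyntheticConfig, simulate_study, write_study

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: single canonical seed for every randomized fixture in the suite
SEED = 0


def small_config(**overrides) -> SyntheticConfig:
    base = dict(
        n_coding=120,
        n_noncoding=110,
        n_planted_pairs=20,
        n_planted_de=10,
        n_planted_de_pairs=4,
        seed=SEED,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study shared across test modules."""
    return simulate_study(small_config())


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """The same compact study written out as the full fixture file set."""
    out = tmp_path_factory.mktemp("study")
    files = write_study(small_config(), out)
    return files
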