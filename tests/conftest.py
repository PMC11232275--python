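import pytest
from hypothesis import settings

import ethnosurvey as es

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kohistan():
    """The packaged Kohistan survey transcription (aggregate mode)."""
    return es.kohistan_fixture()


@pytest.fixture(scope="session")
def kohistan_index(kohistan):
    return es.build_index_table(kohistan)


@pytest.fixture(scope="session")
def small_raw():
    """A small seeded raw-mode synthetic survey for pipeline tests."""
    cfg = es.SyntheticConfig(
        group_sizes={"A": 25, "B": 20, "C": 15},
        n_species=30,
        core_fraction=0.5,
        unique_fractions={"A": 0.1, "B": 0.1, "C": 0.1},
        citation_prob={"core": 0.3, "unique": 0.5, "mixed": 0.4},
        seed=7,
    )
    return es.generate_survey(cfg)
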