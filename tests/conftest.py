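import pytest

from ncrsi import default_dictionaries, default_scenario, generate, score_cohort


@pytest.fixture(scope="session")
def dictionaries():
    return default_dictionaries()


@pytest.fixture(scope="session")
def default_cohort():
    """The default seeded synthetic cohort (sizes 48/82/13)."""
    return generate(default_scenario(), seed=1)


@pytest.fixture(scope="session")
def default_scores(default_cohort, dictionaries):
    return score_cohort(default_cohort, dictionaries)
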