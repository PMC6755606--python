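import pytest
from hypothesis import settings

import jplogp as jp

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_set() -> jp.FixtureSet:
    return jp.make_fixtures(seed=11)


@pytest.fixture(scope="session")
def training_set() -> jp.TrainingSet:
    return jp.make_training_set(seed=7)


@pytest.fixture(scope="session")
def coeff_table(training_set) -> jp.CoefficientTable:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank-deficiency policy is tested explicitly
        return jp.train(training_set)


def typed(smiles: str) -> dict[int, int]:
    return jp.type_molecule(jp.perceive(smiles))
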