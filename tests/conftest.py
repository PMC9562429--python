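import pytest

import spatmap as sm
from _utils import classify_both, prep_experiment


@pytest.fixture(scope="session")
def small_config():
    """A compact two-condition experiment: 440 proteins, 11 compartments."""
    return sm.SimulationConfig(
        n_proteins=440, marker_fraction=0.5, noise_sd=0.1, seed=11
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return prep_experiment(small_config)


@pytest.fixture(scope="session")
def planted_config():
    """Same scale, with ten ER->PM translocating proteins planted."""
    return sm.SimulationConfig(
        n_proteins=440,
        marker_fraction=0.5,
        noise_sd=0.1,
        translocations=tuple((None, "ER", "PM") for _ in range(10)),
        seed=23,
    )


@pytest.fixture(scope="session")
def planted_experiment(planted_config):
    return prep_experiment(planted_config)


@pytest.fixture(scope="session")
def big_config():
    """Study-scale marker coverage (~65 markers per compartment)."""
    return sm.SimulationConfig(
        n_proteins=2002, marker_fraction=0.36, noise_sd=0.1, seed=31
    )


@pytest.fixture(scope="session")
def big_experiment(big_config):
    return prep_experiment(big_config)


@pytest.fixture(scope="session")
def big_classified(big_experiment):
    _, _, combined, marker_set = big_experiment
    return classify_both(combined, marker_set)
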