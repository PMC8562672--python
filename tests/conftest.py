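import numpy as np
import pytest

from glycofibril import (
    CollagenLattice,
    SyntheticScenario,
    load_sugar_registry,
    load_table,
)


@pytest.fixture(scope="session")
def lattice():
    return CollagenLattice()


@pytest.fixture(scope="session")
def ribose_table():
    return load_table("ribose")


@pytest.fixture(scope="session")
def glucose_table():
    return load_table("glucose")


@pytest.fixture(scope="session")
def sugars():
    return load_sugar_registry()


@pytest.fixture
def noiseless_scenario():
    return SyntheticScenario(seed=0, noise_snr=np.inf, background_amp=0.0)


@pytest.fixture
def noisy_scenario():
    return SyntheticScenario(seed=0, noise_snr=50.0)
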