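import numpy as np
import pytest

from oligomerkit import EquilibriumModel, FretTruth, generate_fret_dataset
from oligomerkit.equilibrium import kdiss_from_half_saturation

TRIMER_KDISS = kdiss_from_half_saturation(580.0, 3)  # 252300


@pytest.fixture(scope="session")
def dimer_model():
    return EquilibriumModel(n=2, k_diss=1050.0)


@pytest.fixture(scope="session")
def trimer_model():
    return EquilibriumModel(n=3, k_diss=TRIMER_KDISS)


@pytest.fixture(scope="session")
def noiseless_dimer_dataset():
    return generate_fret_dataset(FretTruth(fret_noise_sd=0.0, n_records=200, seed=11))


@pytest.fixture(scope="session")
def noiseless_trimer_dataset():
    return generate_fret_dataset(
        FretTruth(n=3, k_diss=TRIMER_KDISS, fret_noise_sd=0.0, n_records=200, seed=12)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
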