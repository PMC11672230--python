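import numpy as np
import pytest

import adlayer as al
from adlayer.fitting import FitSpec, fit_simultaneous


@pytest.fixture(scope="session")
def coe3():
    return al.get_protein("COE3")


@pytest.fixture(scope="session")
def stack_ph55():
    return al.make_table1_stack("5.5")


@pytest.fixture(scope="session")
def stack_ph9():
    return al.make_table1_stack("9")


@pytest.fixture(scope="session")
def sim_datasets(stack_ph55):
    """Three-contrast synthetic measurement of the pH 5.5 stack at 2% noise."""
    datasets, truth = al.simulate_contrast_set(
        stack_ph55, noise=al.NoiseModel(seed=7)
    )
    return datasets, truth


@pytest.fixture(scope="session")
def fit_ph55(sim_datasets, coe3):
    """One shared simultaneous fit of the synthetic pH 5.5 datasets."""
    datasets, _ = sim_datasets
    spec = FitSpec(n_slabs=2)
    return fit_simultaneous(datasets, spec, coe3, seed=1), spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
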