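import numpy as np
import pytest

from ramanspine.model import GridConfig
from ramanspine.preprocess import preprocess_dataset
from ramanspine.synth import (GeneratorConfig, generate_dataset, make_axis,
                              noiseless_config)


@pytest.fixture(scope="session")
def axis():
    return make_axis()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def quiet_config():
    return noiseless_config()


@pytest.fixture(scope="session")
def small_fingerprints():
    """Preprocessed 8-per-class dataset shared by the model-stage tests."""
    ds = generate_dataset(n_per_class=8, config=GeneratorConfig(), seed=77)
    return preprocess_dataset(ds.acquisitions), ds.axis


@pytest.fixture(scope="session")
def small_grid():
    """Coarse hyperparameter grid keeping model tests quick."""
    return GridConfig(C1_grid=np.geomspace(0.005, 0.05, 4),
                      C2_grid=np.geomspace(0.1, 5.0, 4), seed=3)
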