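import numpy as np
import pytest

import filletvol as fv


@pytest.fixture(scope="session")
def default_config():
    return fv.PopulationConfig()


@pytest.fixture(scope="session")
def seed7_population():
    return fv.generate_population(fv.PopulationConfig(seed=7))


@pytest.fixture(scope="session")
def seed7_bundle():
    """One full pipeline run on the default 44-fish population, seed 7."""
    return fv.run_pipeline(fv.RunConfig(population=fv.PopulationConfig(seed=7)))


@pytest.fixture
def rng():
    return np.random.default_rng(20311)
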