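import numpy as np
import pytest
from hypothesis import settings

from isofox import Period, datasets

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def carnivores():
    return list(datasets.load_carnivores())


@pytest.fixture(scope="session")
def small_mammals():
    return list(datasets.load_small_mammals())


@pytest.fixture(scope="session")
def prey_sources():
    return datasets.prey_group_sources()


@pytest.fixture(scope="session")
def mp_high_fox_points():
    return datasets.fox_niche_points("high", Period.MP)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240501)
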