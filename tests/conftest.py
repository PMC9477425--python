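import numpy as np
import pytest

from dmfhoi.io import Connectome, normalize_sc
from dmfhoi.synthetic import random_connectome


@pytest.fixture(scope="session")
def sc6() -> Connectome:
    """Small 6-region connectome, strength-normalized for stable dynamics."""
    return normalize_sc(random_connectome(6, seed=5), "strength_to_cap", 0.45)


@pytest.fixture(scope="session")
def sc10() -> Connectome:
    return normalize_sc(random_connectome(10, seed=11), "strength_to_cap", 0.45)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
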