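import numpy as np
import pytest

from bdiv import make_model
from bdiv.fixtures import make_hand_fixtures

#: one parameter point per rate family, used across modules
SIX_MODELS = {
    "M1": (0.5,),
    "M2": (2.0, 0.3),
    "M3": (1.0, 0.5),
    "M4": (0.3, 1.5, 0.8),
    "M5": (0.5, 0.15, 0.1),
    "M6": (0.4, 1.0, 0.5, 0.2),
}


@pytest.fixture(scope="session")
def six_models():
    return {mid: make_model(mid, p) for mid, p in SIX_MODELS.items()}


@pytest.fixture(scope="session")
def hand_trees():
    return make_hand_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20140106)
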