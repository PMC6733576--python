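import numpy as np
import pytest

from hcnax.cable_model import build_model, init_steady_state

_MODEL_CACHE: dict[str, object] = {}


@pytest.fixture(scope="session")
def equilibrated():
    """Lazily built, equilibrated model per variant (shared across tests).

    Callers must not mutate the returned models; protocols copy internally.
    """

    def get(variant: str):
        if variant not in _MODEL_CACHE:
            _MODEL_CACHE[variant] = init_steady_state(build_model(variant))
        return _MODEL_CACHE[variant]

    return get


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
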