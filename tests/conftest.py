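import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecotypesim import PopulationState

settings.register_profile(
    "suite",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_state(effects, present=None, niche=None, origin=None, generation=0) -> PopulationState:
    """Build a PopulationState from plain nested lists / arrays.

    ``niche`` defaults to a half/half split (first half subpopulation 0).
    """
    effects = np.asarray(effects, dtype=float)
    n, l = effects.shape
    if present is None:
        present = np.ones((n, l), dtype=bool)
    else:
        present = np.asarray(present, dtype=bool)
    if niche is None:
        niche = np.repeat(np.array([0, 1], dtype=np.int8), n // 2)
    else:
        niche = np.asarray(niche, dtype=np.int8)
    effects = np.where(present, effects, 0.0)
    if origin is not None:
        origin = np.asarray(origin, dtype=np.int8)
    return PopulationState(
        effects=effects, present=present, niche_of=niche, generation=generation, origin=origin
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
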