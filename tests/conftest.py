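import numpy as np
import pytest
from hypothesis import settings

import replifire as rf

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def mm1_params():
    return rf.ModelParameters(N0=50, J=5, Pout=2e-3, variant="MM1")


@pytest.fixture
def small_lattice(mm1_params):
    """A 200-block lattice with map/mask matching the MM1 defaults."""
    omap = rf.generate_origin_map(200, "continuous")
    mask = rf.generate_region_mask(200, 0.0, "block")
    state = rf.init_state(mm1_params, omap, mask)
    return state, omap, mask


def make_state(pattern: str) -> rf.LatticeState:
    """Lattice state from a binary string like '0011100'."""
    blocks = np.array([int(c) for c in pattern], dtype=np.uint8)
    state = rf.LatticeState(blocks=blocks)
    state.fired_total = state.eye_count  # consistent bookkeeping
    return state
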