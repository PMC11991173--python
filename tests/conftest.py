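import warnings

import numpy as np
import pytest

from polycma.cma import CmaSampler, seed_state
from polycma.energetics import InteractionSet
from polycma.lattice import Configuration, LatticeSpec, build_neighbor_table, init_chain

# tiny boxes are used deliberately throughout the suite; the coil-size guard
# warning is informational there
warnings.filterwarnings("ignore", message="box edge .* coil-size guard")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_chain(rng):
    """N=16 chain in a 32x32 box, freshly grown."""
    return init_chain(16, LatticeSpec(32), rng)


@pytest.fixture
def relaxed_chain(rng):
    """N=16 chain after a short athermal relaxation."""
    config = init_chain(16, LatticeSpec(32), rng)
    sampler = CmaSampler(config, InteractionSet.athermal(), seed=7)
    sampler.run(500)
    return config


def chain_from_uv(L: int, uv_list) -> Configuration:
    """Build a configuration from explicit axial coordinates."""
    sites = [(u % L) * L + (v % L) for u, v in uv_list]
    cfg = Configuration.from_chain_sites(L, sites)
    return cfg


def straight_rod(L: int, N: int, v: int = 0) -> Configuration:
    """N collinear beads along the u axis."""
    return chain_from_uv(L, [(k, v) for k in range(N)])
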