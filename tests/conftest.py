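import numpy as np
import pytest

from nednsim import Composition, ModelParams


@pytest.fixture
def two_genus_params():
    """Hand-oracle parameters: alpha=(0.5,0.25), cross effects 0.1 / -0.2."""
    return ModelParams(
        ("a", "b"),
        np.array([0.5, 0.25]),
        np.array([[0.0, -0.2], [0.1, 0.0]]),
    )


@pytest.fixture
def two_genus_state():
    return Composition(("a", "b"), np.array([0.4, 0.2]))


@pytest.fixture
def two_basin_system():
    """A 4-genus community with two mutually exclusive stable blocks.

    Within-block facilitation (+0.1) and strong cross-block inhibition
    (-2.0) make {a, b} and {c, d} alternative attractors; a start dominated
    by one block settles into that block's fixed point with the other block
    pinned at the extinction floor.
    """
    genera = ("a", "b", "c", "d")
    alpha = np.full(4, 0.5)
    beta = np.array(
        [
            [0.0, 0.1, -2.0, -2.0],
            [0.1, 0.0, -2.0, -2.0],
            [-2.0, -2.0, 0.0, 0.1],
            [-2.0, -2.0, 0.1, 0.0],
        ]
    )
    return ModelParams(genera, alpha, beta)


def biased_starts(n_block1, n_block2, seed=0):
    """Starts for the two-basin system, dominated by block 1 or block 2."""
    rng = np.random.default_rng(seed)
    genera = ("a", "b", "c", "d")
    starts = []
    for conc in [(5, 5, 0.2, 0.2)] * n_block1 + [(0.2, 0.2, 5, 5)] * n_block2:
        v = rng.dirichlet(conc)
        v = np.maximum(v, 1e-6)
        starts.append(Composition(genera, v / v.sum()))
    return starts
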