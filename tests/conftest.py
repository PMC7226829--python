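import numpy as np
import pytest

from imdn.data_io import AssociationMatrix, ExpressionTable, build_weight_matrix
from imdn.model import ModelConfig
from imdn.synthetic import WorldParams, build_simnet, generate_world


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_assoc():
    """4 miRNAs x 3 diseases with a mix of dense and sparse rows."""
    R = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ],
        dtype=float,
    )
    return AssociationMatrix(
        ("m-a", "m-b", "m-c", "m-d"), ("d-x", "d-y", "d-z"), R
    )


@pytest.fixture
def small_world():
    """A compact synthetic world for integration-level tests."""
    return generate_world(WorldParams(nm=25, nd=15, nl=3, tau=0.8), seed=7)


@pytest.fixture
def small_problem(small_world):
    """Training-ready (assoc, weights, simnet) triple from the small world."""
    world = small_world
    weights = build_weight_matrix(world.assoc, world.expression)
    simnet = build_simnet(world.assoc, world.fs, world.fs_mask)
    return world.assoc, weights, simnet


@pytest.fixture
def quick_config():
    return ModelConfig(latent_dim=4, max_epochs=150, learning_rate=0.1, seed=3)


def random_instance(rng, nm=6, nd=5, nl=3):
    """A random small (R, W, S_norm, M, D) tuple for oracle comparisons."""
    R = (rng.random((nm, nd)) < 0.4).astype(float)
    W = rng.random((nm, nd))
    S = rng.random((nm, nm))
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 0.0)
    S /= S.sum(axis=1, keepdims=True)
    M = rng.normal(0, 0.5, (nm, nl))
    D = rng.normal(0, 0.5, (nd, nl))
    return R, W, S, M, D
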