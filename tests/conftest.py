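import numpy as np
import pytest

from grmt import (
    BuildParams,
    ErrorModel,
    MutationMatrix,
    MutationTree,
    SimConfig,
    simulate,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """7 cells × 4 mutations with some missing entries, binary mode."""
    data = rng.integers(0, 2, (7, 4))
    mask = rng.random((7, 4)) < 0.2
    return MutationMatrix(data=data, missing_mask=mask)


@pytest.fixture
def chain_tree():
    """root → 1+ → 2+ → 3+ over M=3, k=0."""
    tree = MutationTree(3, 0)
    tree.parent[1] = 0
    tree.parent[2] = 1
    tree.parent[3] = 2
    return tree


@pytest.fixture
def error_model():
    return ErrorModel(alpha=0.01, beta=0.2)


@pytest.fixture
def sim_small():
    """Small low-noise simulated dataset with known ground truth."""
    return simulate(SimConfig(N=80, M=12, alpha=0.005, beta=0.05, eta=0.05,
                              rho=0.0, seed=7))


def make_params(**kw):
    defaults = dict(alpha=0.01, beta=0.2, k=0, lam=0.7, kappa=1.0)
    defaults.update(kw)
    return BuildParams(**defaults)
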