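import numpy as np
import pytest

from cadm import DistanceMatrix, GTRParameters, random_additive_tree, tree_to_distances


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


@pytest.fixture
def labels4():
    return ["a", "b", "c", "d"]


@pytest.fixture
def dm4(labels4):
    values = np.array(
        [
            [0.0, 1.0, 4.0, 5.0],
            [1.0, 0.0, 3.0, 4.0],
            [4.0, 3.0, 0.0, 7.0],
            [5.0, 4.0, 7.0, 0.0],
        ]
    )
    return DistanceMatrix(values, labels4)


@pytest.fixture
def random_dm_factory():
    """Random symmetric distance matrices (not necessarily additive)."""

    def make(m, seed, labels=None):
        r = np.random.default_rng(seed)
        v = r.random((m, m))
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        return DistanceMatrix(v, labels or [f"t{i:02d}" for i in range(m)])

    return make


@pytest.fixture
def additive_dm_factory():
    def make(m, seed):
        r = np.random.default_rng(seed)
        return tree_to_distances(random_additive_tree(m, r))

    return make


@pytest.fixture
def default_gtr():
    return GTRParameters()
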