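import numpy as np
import pytest
import scipy.sparse as sp

from monoseq.network import GeneNetwork
from monoseq.megdetect import StageDesign


@pytest.fixture
def path_network():
    """3-gene path A-B-C with degrees (1, 2, 1)."""
    A = sp.csr_matrix(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8))
    return GeneNetwork(["A", "B", "C"], A)


@pytest.fixture
def edgeless_network():
    return GeneNetwork(["A", "B", "C"], sp.csr_matrix((3, 3), dtype=np.int8))


@pytest.fixture
def three_stage_design():
    """Six samples in three stages of two."""
    return StageDesign([f"s{i}" for i in range(6)], [1, 1, 2, 2, 3, 3])


def random_network(p, density, rng):
    """Random symmetric zero-diagonal adjacency (test helper)."""
    upper = sp.random(p, p, density=density, random_state=rng, format="coo")
    mask = upper.row < upper.col
    r, c = upper.row[mask], upper.col[mask]
    data = np.ones(2 * len(r), dtype=np.int8)
    A = sp.coo_matrix(
        (data, (np.concatenate([r, c]), np.concatenate([c, r]))), shape=(p, p)
    ).tocsr()
    A.data[:] = 1
    return GeneNetwork([f"g{k}" for k in range(p)], A)
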