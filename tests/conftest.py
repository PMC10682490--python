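import numpy as np
import pandas as pd
import pytest

from conngrad.atlas import AtlasPartition, default_partition
from conngrad.connectome import Connectome


@pytest.fixture(scope="session")
def partition226():
    return default_partition()


@pytest.fixture
def small_partition():
    """4 nodes in two 2-node networks."""
    return AtlasPartition(node_ids=(1, 2, 3, 4),
                          network_of_node=("A", "A", "B", "B"))


@pytest.fixture
def small_connectome():
    """4-node connectome with hand-set block values.

    r12=0.5, r34=0.1, r13=0.2, r14=0.2, r23=0.4, r24=0.0.
    """
    m = np.array([
        [1.0, 0.5, 0.2, 0.2],
        [0.5, 1.0, 0.4, 0.0],
        [0.2, 0.4, 1.0, 0.1],
        [0.2, 0.0, 0.1, 1.0],
    ])
    return Connectome(m)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_block_connectomes(
    rng, n_subjects, n_nodes, shift_edges=None, delta=0.0, noise=0.1
):
    """Symmetric noise matrices, optionally with a planted edge shift."""
    conns = []
    for _ in range(n_subjects):
        m = rng.standard_normal((n_nodes, n_nodes)) * noise
        m = (m + m.T) / 2
        if shift_edges:
            for i, j in shift_edges:
                m[i, j] += delta
                m[j, i] += delta
        np.fill_diagonal(m, 0.0)
        conns.append(m)
    return conns


@pytest.fixture
def covariates_frame():
    def build(n, rng, sites=("s1", "s2")):
        return pd.DataFrame({
            "age": rng.integers(18, 66, n),
            "sex": rng.choice(["female", "male"], n),
            "education": rng.normal(12, 3, n),
            "site": [sites[i % len(sites)] for i in range(n)],
        })
    return build
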