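import numpy as np
import pytest

from avhnet.data_io import load_packaged_node_table


@pytest.fixture(scope="session")
def node_table():
    return load_packaged_node_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_binary_graph(rng, n, p):
    """Erdos-Renyi adjacency as a BinaryGraph-compatible uint8 matrix."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1).astype(np.uint8)
    return adj | adj.T
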