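import numpy as np
import pytest

from gnmgates import (
    ContactNetwork,
    ResidueRecord,
    build_kirchhoff,
    eigendecompose,
    generate_synthetic_structure,
)


def make_records(n):
    """Dummy residue records with author numbers 1..n."""
    return [
        ResidueRecord("A", i + 1, "", "ALA", np.zeros(3)) for i in range(n)
    ]


def network_from_adjacency(adj, gamma=1.0):
    """Build a ContactNetwork directly from a boolean adjacency matrix
    (for graph-level tests that need no geometry)."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    matrix = -gamma * adj.astype(float)
    np.fill_diagonal(matrix, 0.0)
    np.fill_diagonal(matrix, gamma * adj.sum(axis=1))
    return ContactNetwork(matrix=matrix, cutoff=7.0, gamma=gamma,
                          index_map=make_records(n))


def random_connected_network(n, seed, p=0.25, gamma=1.0):
    """Seeded Erdos-Renyi contact graph, resampled until connected."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        upper = rng.random((n, n)) < p
        adj = np.triu(upper, 1)
        adj = adj | adj.T
        net = network_from_adjacency(adj, gamma=gamma)
        if eigendecompose(net).zero_mode_count == 1:
            return net
    raise AssertionError(f"no connected graph found for n={n}, seed={seed}")


def connected_cluster(n, seed, spacing=3.8):
    """Synthetic packed cluster whose 7 A contact graph is connected."""
    for s in range(seed, seed + 50):
        structure = generate_synthetic_structure("cluster", n, spacing, seed=s)
        net = build_kirchhoff(structure)
        if eigendecompose(net).zero_mode_count == 1:
            return structure, net
    raise AssertionError(f"no connected cluster found from seed {seed}")


@pytest.fixture(scope="session")
def cluster30():
    structure, net = connected_cluster(30, seed=7)
    return structure, net


@pytest.fixture(scope="session")
def cluster30_spectrum(cluster30):
    _, net = cluster30
    return eigendecompose(net)
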