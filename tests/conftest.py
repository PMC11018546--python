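import numpy as np
import pytest

import cohesionnet as cn


def make_network(edges, communities, nodes=None):
    """Small TissueNetwork helper: edges {(a,b): w}, communities {label: set}."""
    if nodes is None:
        nodes = sorted({g for e in edges for g in e} | {g for c in communities.values() for g in c})
    return cn.TissueNetwork(
        list(nodes),
        {tuple(sorted(e)): w for e, w in edges.items()},
        {k: frozenset(v) for k, v in communities.items()},
    )


@pytest.fixture(scope="session")
def tiny_config():
    """Two-block fixture small enough for fast end-to-end runs."""
    return cn.SimulationConfig(
        n_genes=60,
        n_controls=120,
        n_cases=6,
        communities=(cn.CommunitySpec(30, 0.9), cn.CommunitySpec(30, 0.85)),
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_controls(tiny_config):
    return cn.generate_controls(tiny_config)


@pytest.fixture(scope="session")
def tiny_reference(tiny_controls):
    return cn.build_reference(
        tiny_controls, power=6, min_community_size=10, n_permutations=50
    )


@pytest.fixture(scope="session")
def tiny_models(tiny_controls, tiny_reference):
    return cn.fit_all_edges(tiny_controls, tiny_reference.network)


def floyd_warshall_efficiency(nodes, edges):
    """Independent brute-force oracle for weighted community efficiency.

    Plain O(n^3) Floyd-Warshall over path lengths 1/w; disconnected pairs
    contribute zero.
    """
    n = len(nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for (a, b), w in edges.items():
        dist[pos[a], pos[b]] = dist[pos[b], pos[a]] = 1.0 / w
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))
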