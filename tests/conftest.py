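"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from seqspace.fixtures import load_fixtures
from seqspace.simulate import SpaceConfig, functional_index, neighbor_indices


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


def explicit_graph(config: SpaceConfig) -> tuple[nx.Graph, np.ndarray]:
    """Independent oracle: materialise the whole functional subgraph.

    Enumerates every sequence index, evaluates functionality, and builds the
    explicit graph of functional single-mutation neighbours with networkx.
    Only usable for small spaces (A**L up to ~10**4).
    """
    n = config.size
    idx = np.arange(n)
    func = functional_index(config, idx)
    graph = nx.Graph()
    fidx = idx[func]
    graph.add_nodes_from(fidx.tolist())
    for block in np.array_split(fidx, max(1, len(fidx) // 2048)):
        if block.size == 0:
            continue
        nbrs = neighbor_indices(config, block)
        for i, row in zip(block.tolist(), nbrs):
            for j in row[func[row]].tolist():
                graph.add_edge(i, j)
    return graph, func


def oracle_cluster(config: SpaceConfig) -> set[int]:
    """Connected component of the start sequence via networkx."""
    graph, func = explicit_graph(config)
    if not func[config.start_index]:
        return set()
    return set(nx.node_connected_component(graph, config.start_index))


def sample_discrete_power_law(
    tau: float, n: int, s_min: int, rng: np.random.Generator, s_max: int = 10**6
) -> np.ndarray:
    """Inverse-CDF sampler for P(s) proportional to s**(-tau), s >= s_min."""
    support = np.arange(s_min, s_max + 1, dtype=np.float64)
    weights = support ** (-tau)
    cdf = np.cumsum(weights) / weights.sum()
    return support[np.searchsorted(cdf, rng.random(n))]
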