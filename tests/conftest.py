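import numpy as np
import pytest

from graphrf import FeatureGraph, SimulationConfig, generate_ba_graph, simulate_dataset


@pytest.fixture
def path_graph():
    """0-1-2-3-4 path."""
    return FeatureGraph.from_edges(5, [(0, 1), (1, 2), (2, 3), (3, 4)])


@pytest.fixture
def triangle():
    return FeatureGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture(params=[0, 1, 2])
def random_graph(request):
    """Erdos-Renyi-ish random graphs with <= 50 nodes for oracle comparisons."""
    rng = np.random.default_rng(request.param)
    n = int(rng.integers(10, 50))
    edges = set()
    for _ in range(int(rng.integers(n, 3 * n))):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return FeatureGraph.from_edges(n, edges)


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset reused across test modules."""
    return simulate_dataset(SimulationConfig(p=200, n=150, p0=20, seed=42))
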