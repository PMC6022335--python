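import numpy as np
import pytest

from gesop import WeightedNetwork


@pytest.fixture
def triangle():
    """A-B 0.9, B-C 0.8, A-C 0.5: max forest is {A-B, B-C} (weight 1.7)."""
    net = WeightedNetwork()
    net.add_edge("A", "B", 0.9)
    net.add_edge("B", "C", 0.8)
    net.add_edge("A", "C", 0.5)
    return net


@pytest.fixture
def path4():
    net = WeightedNetwork()
    for a, b in [("A", "B"), ("B", "C"), ("C", "D")]:
        net.add_edge(a, b, 0.5)
    return net


@pytest.fixture
def k4():
    net = WeightedNetwork()
    names = ["A", "B", "C", "D"]
    for i in range(4):
        for j in range(i + 1, 4):
            net.add_edge(names[i], names[j], 0.5)
    return net


def random_network(rng: np.random.Generator, n_nodes: int = 30,
                   p: float = 0.2, distinct: bool = False) -> WeightedNetwork:
    """Erdős–Rényi weighted network; optionally strictly distinct weights."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    net = WeightedNetwork(nodes=names)
    pairs = [(names[i], names[j]) for i in range(n_nodes)
             for j in range(i + 1, n_nodes)]
    keep = rng.random(len(pairs)) < p
    weights = rng.uniform(0.01, 1.0, size=len(pairs))
    if distinct:
        order = np.argsort(weights)
        weights[order] = np.linspace(0.01, 0.99, len(pairs))
    for (a, b), k, w in zip(pairs, keep, weights):
        if k:
            net.add_edge(a, b, round(float(w), 6))
    return net
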