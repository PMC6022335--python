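"""The two-step optimizer: forest optimality, hubs, re-addition, guarantees."""

import itertools

import networkx as nx
import numpy as np
import pytest

from gesop import (GesopConfig, WeightedNetwork, add_hub_edges, find_hubs,
                   gesop, gesop_detailed, max_relevance_forest,
                   write_edge_list)
from conftest import random_network

# ---------------------------------------------------------------------------
# step 1: maximum-relevance forest
# ---------------------------------------------------------------------------

def test_triangle_forest(triangle):
    res = max_relevance_forest(triangle)
    assert res.forest.edge_weights == {("A", "B"): 0.9, ("B", "C"): 0.8}
    assert res.removed == {("A", "C"): 0.5}


def test_tree_input_is_unchanged(path4):
    res = max_relevance_forest(path4)
    assert res.forest == path4 and res.removed == {}


def test_disconnected_input_spans_components():
    net = WeightedNetwork()
    for a, b, w in [("A", "B", 0.9), ("B", "C", 0.8), ("A", "C", 0.7),
                    ("X", "Y", 0.6), ("Y", "Z", 0.5), ("X", "Z", 0.4)]:
        net.add_edge(a, b, w)
    res = max_relevance_forest(net)
    assert res.forest.n_edges == 4  # 6 nodes, 2 components
    assert res.forest.nodes == net.nodes


def test_empty_network_gives_empty_forest():
    res = max_relevance_forest(WeightedNetwork(nodes=["A", "B"]))
    assert res.forest.n_edges == 0 and res.forest.nodes == {"A", "B"}


def _brute_force_max_forest_weight(net: WeightedNetwork) -> float:
    """Exhaustive maximum over all spanning forests (acyclic |V|-C subsets)."""
    edges = list(net.edge_weights.items())
    n_comp = nx.number_connected_components(net.to_networkx())
    target = net.n_nodes - n_comp
    best = -1.0
    for combo in itertools.combinations(edges, target):
        parent = {n: n for n in net.nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for (a, b), _ in combo:
            ra, rb = find(a), find(b)
            if ra == rb:
                ok = False
                break
            parent[ra] = rb
        if ok:
            best = max(best, sum(w for _, w in combo))
    return best


@pytest.mark.parametrize("seed", range(12))
def test_forest_weight_is_exhaustively_optimal(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    net = random_network(rng, n_nodes=n, p=0.6)
    res = max_relevance_forest(net)
    got = sum(res.forest.edge_weights.values())
    assert got == pytest.approx(_brute_force_max_forest_weight(net))
    n_comp = nx.number_connected_components(net.to_networkx())
    assert res.forest.n_edges == n - n_comp


@pytest.mark.parametrize("seed", range(5))
def test_forest_matches_networkx_cross_check(seed):
    """With distinct weights the maximum spanning forest is unique."""
    rng = np.random.default_rng(100 + seed)
    net = random_network(rng, n_nodes=25, p=0.25, distinct=True)
    res = max_relevance_forest(net)
    ref = nx.Graph()
    ref.add_nodes_from(net.nodes)
    ref.add_edges_from(net.to_networkx().edges(data=True))
    ref_edges = {tuple(sorted((a, b)))
                 for a, b, _ in nx.maximum_spanning_edges(ref)}
    assert set(res.forest.edge_weights) == ref_edges


def test_heaviest_edge_always_kept():
    rng = np.random.default_rng(9)
    for seed in range(10):
        net = random_network(np.random.default_rng(seed), n_nodes=12, p=0.4,
                             distinct=True)
        if net.n_edges == 0:
            continue
        top = max(net.iter_edges(), key=lambda e: e.weight)
        res = max_relevance_forest(net)
        assert res.forest.has_edge(top.gene_a, top.gene_b)


def test_equal_weight_tie_break_is_canonical():
    # A-B and A-C tie at 0.9 and form a cycle with B-C; canonical pair
    # ordering must keep A-B first deterministically.
    net = WeightedNetwork()
    net.add_edge("A", "B", 0.9)
    net.add_edge("A", "C", 0.9)
    net.add_edge("B", "C", 0.9)
    res = max_relevance_forest(net)
    assert set(res.forest.edge_weights) == {("A", "B"), ("A", "C")}


# ---------------------------------------------------------------------------
# step 2: hubs and re-addition
# ---------------------------------------------------------------------------

def test_star_center_is_the_only_hub():
    net = WeightedNetwork()
    for leaf in "BCDE":
        net.add_edge("A", leaf, 0.8)
    hubs = find_hubs(net)
    assert hubs.mean_degree == pytest.approx(8 / 5)
    assert hubs.hubs == {"A"}


def test_regular_graph_has_no_hubs():
    net = WeightedNetwork()
    cyc = ["A", "B", "C", "D", "E", "F"]
    for i in range(6):
        net.add_edge(cyc[i], cyc[(i + 1) % 6], 0.5)
    assert find_hubs(net).hubs == frozenset()


def test_path_interior_nodes_are_hubs(path4):
    hubs = find_hubs(path4)
    assert hubs.mean_degree == pytest.approx(1.5)
    assert hubs.hubs == {"B", "C"}


def test_mean_degree_counts_isolated_nodes():
    net = WeightedNetwork(nodes=["Z1", "Z2"])
    net.add_edge("A", "B", 0.5)
    assert find_hubs(net).mean_degree == pytest.approx(2 / 4)
    assert find_hubs(net).hubs == {"A", "B"}


def _prune_with_removed(removed):
    forest = WeightedNetwork()
    forest.add_edge("H", "A", 0.9)
    forest.add_edge("H", "B", 0.9)
    forest.add_edge("B", "X", 0.9)
    from gesop import PruneResult
    return PruneResult(forest=forest, removed=removed)


def test_readd_rules():
    hubs = find_hubs(_prune_with_removed({}).forest)
    assert "H" in hubs.hubs and "X" not in hubs.hubs  # mean 1.5; H,B deg 2
    cfg = GesopConfig(th_beta=0.7)
    # hub-incident, above threshold -> added
    out = add_hub_edges(_prune_with_removed({("H", "X"): 0.8}), hubs, cfg)
    assert out.has_edge("H", "X")
    # hub-incident, below threshold -> not added
    out = add_hub_edges(_prune_with_removed({("H", "X"): 0.6}), hubs, cfg)
    assert not out.has_edge("H", "X")
    # both endpoints non-hub -> never added
    out = add_hub_edges(_prune_with_removed({("A", "X"): 0.95}), hubs, cfg)
    assert not out.has_edge("A", "X")
    # boundary: inclusive comparison admits exactly th_beta
    out = add_hub_edges(_prune_with_removed({("H", "X"): 0.7}), hubs, cfg)
    assert not out.has_edge("H", "X")
    out = add_hub_edges(_prune_with_removed({("H", "X"): 0.7}), hubs,
                        GesopConfig(th_beta=0.7, inclusive_threshold=True))
    assert out.has_edge("H", "X")


# ---------------------------------------------------------------------------
# the composition
# ---------------------------------------------------------------------------

def test_high_th_beta_returns_the_forest(triangle):
    out = gesop(triangle, GesopConfig(th_beta=0.95))
    assert out == max_relevance_forest(triangle).forest


def test_vacuous_th_beta_restores_all_hub_incident_edges():
    rng = np.random.default_rng(21)
    net = random_network(rng, n_nodes=20, p=0.4)
    cfg = GesopConfig(th_beta=0.0, inclusive_threshold=True)
    final, prune, hubs, _ = gesop_detailed(net, cfg)
    expect = dict(prune.forest.edge_weights)
    expect.update({p: w for p, w in prune.removed.items()
                   if p[0] in hubs.hubs or p[1] in hubs.hubs})
    assert final.edge_weights == expect


def _naive_gesop(net: WeightedNetwork, th_beta: float) -> set:
    """Independent stepwise reference: library forest + naive steps 2a/2b.

    Requires distinct weights so the maximum spanning forest is unique.
    """
    g = net.to_networkx()
    forest_edges = {tuple(sorted((a, b)))
                    for a, b, _ in nx.maximum_spanning_edges(g)}
    deg = {n: 0 for n in net.nodes}
    for a, b in forest_edges:
        deg[a] += 1
        deg[b] += 1
    mean = 2 * len(forest_edges) / len(deg)
    hubs = {n for n, d in deg.items() if d > mean}
    final = set(forest_edges)
    for (a, b), w in net.edge_weights.items():
        if (a, b) not in forest_edges and (a in hubs or b in hubs) and w > th_beta:
            final.add((a, b))
    return final


@pytest.mark.parametrize("seed", range(6))
def test_gesop_matches_independent_stepwise_reference(seed):
    rng = np.random.default_rng(300 + seed)
    net = random_network(rng, n_nodes=50, p=0.25, distinct=True)  # ~300 edges
    final = gesop(net, GesopConfig(th_beta=0.7))
    assert set(final.edge_weights) == _naive_gesop(net, 0.7)


@pytest.mark.parametrize("seed", range(10))
def test_structural_guarantees(seed):
    rng = np.random.default_rng(400 + seed)
    net = random_network(rng, n_nodes=30, p=0.2)
    out = gesop(net, GesopConfig())
    # node conservation and subset property
    assert out.nodes == net.nodes
    assert set(out.edge_weights) <= set(net.edge_weights)
    n_comp = nx.number_connected_components(net.to_networkx())
    assert net.n_nodes - n_comp <= out.n_edges <= net.n_edges


def test_th_beta_monotonicity():
    rng = np.random.default_rng(55)
    net = random_network(rng, n_nodes=40, p=0.3)
    counts = [gesop(net, GesopConfig(th_beta=t)).n_edges
              for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
    assert counts == sorted(counts, reverse=True)


def test_deterministic_serialization(tmp_path):
    rng = np.random.default_rng(77)
    net = random_network(rng, n_nodes=30, p=0.3)
    paths = []
    for i in range(2):
        out = gesop(net, GesopConfig())
        p = tmp_path / f"run{i}.tsv"
        write_edge_list(out, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_report_diff_pct(triangle):
    _, _, _, rep = gesop_detailed(triangle, GesopConfig(th_beta=0.95))
    assert rep.n_edges_input == 3 and rep.n_edges_final == 2
    assert rep.diff_pct == pytest.approx(-100 / 3)
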