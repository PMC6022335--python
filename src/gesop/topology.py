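"""Scale-free topology indicators for a network (a Table-style report row).

Indicators: mean clustering coefficient, characteristic path length (CPL),
diameter, graph density and the power-law exponent γ of the degree
distribution.  Biological networks are expected to be sparse and
scale-free: low clustering/density, high CPL/diameter, degree distribution
``P(k) ∝ k^(−γ)`` with a clearly positive γ.

Conventions for disconnected networks: CPL and diameter are taken over all
*connected* unordered pairs (disconnected pairs are excluded and counted),
matching the behaviour of the usual network-analysis desktop tools and
keeping comparisons defined after aggressive pruning.

γ is, by default, the magnitude of the least-squares slope of
``log P(k)`` vs ``log k`` over the observed positive degrees — the classic
log-log regression fit.  A continuous maximum-likelihood (Hill-type)
estimate is available as an alternative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netcore import UndefinedMetricError, WeightedNetwork

logger = logging.getLogger("gesop.topology")


@dataclass
class TopologyReport:
    """All indicators for one network; ``None`` marks an undefined entry."""

    clustering: float | None
    cpl: float | None
    diameter: int | None
    density: float | None
    gamma: float | None
    n_components: int

    def to_dict(self) -> dict:
        return {
            "clustering": self.clustering, "cpl": self.cpl,
            "diameter": self.diameter, "density": self.density,
            "gamma": self.gamma, "n_components": self.n_components,
        }


# ---------------------------------------------------------------------------
# path-based indicators
# ---------------------------------------------------------------------------

def _distance_stats(g: nx.Graph) -> tuple[float, int, int, int]:
    """(sum of pair distances, n connected pairs, diameter, n disconnected pairs).

    BFS from every node within its component; exact, no sampling.
    """
    total = 0
    diam = 0
    pairs = 0
    comp_sizes = []
    for comp in nx.connected_components(g):
        comp_sizes.append(len(comp))
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for node in comp:
            lengths = nx.single_source_shortest_path_length(sub, node)
            total += sum(lengths.values())
            diam = max(diam, max(lengths.values()))
        pairs += len(comp) * (len(comp) - 1) // 2
    n = g.number_of_nodes()
    all_pairs = n * (n - 1) // 2
    return total / 2, pairs, diam, all_pairs - pairs


def characteristic_path_length(net: WeightedNetwork) -> float:
    """Mean unweighted shortest-path length over connected unordered pairs."""
    g = net.to_networkx()
    total, pairs, _, skipped = _distance_stats(g)
    if pairs == 0:
        raise UndefinedMetricError("CPL undefined: no connected pair of nodes")
    if skipped:
        logger.info("CPL: %d disconnected pairs excluded", skipped)
    return total / pairs


def diameter(net: WeightedNetwork) -> int:
    """Maximum shortest-path length over connected pairs."""
    g = net.to_networkx()
    _, pairs, diam, _ = _distance_stats(g)
    if pairs == 0:
        raise UndefinedMetricError("diameter undefined: no connected pair")
    return diam


# ---------------------------------------------------------------------------
# local structure
# ---------------------------------------------------------------------------

def avg_clustering(net: WeightedNetwork) -> float:
    """Mean local clustering coefficient over all nodes.

    A node's coefficient is the fraction of realizable links among its
    neighbours that exist; nodes of degree < 2 contribute 0.
    """
    if net.n_nodes == 0:
        raise UndefinedMetricError("clustering undefined for empty network")
    return nx.average_clustering(net.to_networkx(), count_zeros=True)


def density(net: WeightedNetwork) -> float:
    """``2|E| / (|V|(|V|−1))``; undefined for fewer than two nodes."""
    if net.n_nodes < 2:
        raise UndefinedMetricError("density undefined for < 2 nodes")
    return nx.density(net.to_networkx())


# ---------------------------------------------------------------------------
# power-law exponent
# ---------------------------------------------------------------------------

def fit_powerlaw_loglog(k: np.ndarray, pk: np.ndarray) -> float:
    """γ as the magnitude of the least-squares slope of log P(k) vs log k.

    Only strictly positive ``k`` and ``P(k)`` enter the fit; at least three
    points are required.
    """
    k = np.asarray(k, dtype=float)
    pk = np.asarray(pk, dtype=float)
    mask = (k > 0) & (pk > 0)
    k, pk = k[mask], pk[mask]
    if k.size < 3:
        raise UndefinedMetricError(
            f"power-law fit needs >= 3 positive degree frequencies, got {k.size}")
    slope = np.polyfit(np.log(k), np.log(pk), 1)[0]
    return float(abs(slope))


def gamma_mle(degrees: np.ndarray, k_min: int | None = None) -> float:
    """Continuous-approximation maximum-likelihood exponent estimate,
    ``1 + n / Σ ln(k_i / (k_min − 1/2))`` over degrees ≥ k_min."""
    degrees = np.asarray([d for d in degrees if d > 0], dtype=float)
    if k_min is None:
        k_min = int(degrees.min()) if degrees.size else 1
    sel = degrees[degrees >= k_min]
    if sel.size < 3:
        raise UndefinedMetricError("MLE fit needs >= 3 degrees >= k_min")
    return float(1.0 + sel.size / np.sum(np.log(sel / (k_min - 0.5))))


def powerlaw_gamma(net: WeightedNetwork, method: str = "linear") -> float:
    """Power-law exponent γ of the degree distribution.

    ``method="linear"`` (default) fits log P(k) vs log k by least squares
    over degrees k ≥ 1; ``method="mle"`` uses the continuous ML estimate.
    Requires at least 3 distinct positive degrees (a regular graph has no
    defined exponent).
    """
    degs = np.array([d for d in net.degrees().values() if d > 0])
    if np.unique(degs).size < 3:
        raise UndefinedMetricError(
            "gamma undefined: fewer than 3 distinct positive degrees")
    if method == "mle":
        return gamma_mle(degs)
    if method != "linear":
        raise ValueError(f"unknown fit method {method!r}")
    k, counts = np.unique(degs, return_counts=True)
    pk = counts / degs.size
    return fit_powerlaw_loglog(k, pk)


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------

def topology_report(net: WeightedNetwork) -> TopologyReport:
    """Assemble every indicator; undefined entries become ``None``."""
    def attempt(fn):
        try:
            return fn(net)
        except UndefinedMetricError as exc:
            logger.info("topology_report: %s", exc)
            return None

    n_components = nx.number_connected_components(net.to_networkx())
    return TopologyReport(
        clustering=attempt(avg_clustering),
        cpl=attempt(characteristic_path_length),
        diameter=attempt(diameter),
        density=attempt(density),
        gamma=attempt(powerlaw_gamma),
        n_components=n_components,
    )
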