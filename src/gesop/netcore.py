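"""Core domain types for weighted undirected gene networks, plus text I/O.

The central object of every pipeline stage is :class:`WeightedNetwork`: a
simple undirected graph whose nodes are gene identifiers and whose edges
carry a relevance weight in ``[0, 1]`` (a correlation magnitude or a
normalized mutual information).  Isolated nodes are first-class citizens —
the optimizer guarantees node conservation, so a network must be able to
represent genes with no surviving relationship.

Supported interchange formats:

* weighted edge lists (TSV/CSV, 2 or 3 columns) with a sidecar ``.nodes``
  roster so isolated nodes survive a round trip;
* Cytoscape SIF (``nodeA relation nodeB``, weight defaults to 1.0);
* GraphML with a ``weight`` edge attribute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

import networkx as nx

logger = logging.getLogger("gesop")

MEASURES = ("kendall", "spearman", "su")

#: weights are serialized with this many decimals; equality of a written and
#: re-read network is exact when weights are representable at this precision
WEIGHT_DECIMALS = 6


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class GesopError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(GesopError):
    """A malformed input file (wrong columns, bad weight, self-loop...)."""


class ConfigError(GesopError):
    """An invalid configuration value."""


class UndefinedMeasureError(GesopError):
    """A pairwise measure is undefined (constant vector, zero entropy)."""


class UndefinedMetricError(GesopError):
    """A topology indicator is undefined for this network."""


class EvaluationError(GesopError):
    """Gold-standard comparison is impossible (e.g. no shared genes)."""


# ---------------------------------------------------------------------------
# pairs and records
# ---------------------------------------------------------------------------

def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered pair ``{a, b}`` in canonical (lexicographic) order.

    Canonical ordering gives deterministic serialization and a stable
    tie-break for equal-weight edges in the optimizer.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


class EdgeRecord(NamedTuple):
    """One weighted relationship, endpoints stored in canonical order."""

    gene_a: str
    gene_b: str
    weight: float

    @classmethod
    def make(cls, a: str, b: str, weight: float) -> "EdgeRecord":
        a, b = canonical_pair(a, b)
        return cls(a, b, float(weight))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class GesopConfig:
    """Thresholds and conventions shared by the pipeline stages.

    Parameters
    ----------
    th_alpha : float
        Cut-off applied to the pairwise measure when building the input
        coexpression network.  The default 0.5 is deliberately permissive so
        the construction yields an over-connected network for the optimizer
        to prune.
    th_beta : float
        Cut-off for re-adding pruned edges to hubs in the optimizer's second
        step; 0.7 is the conventional "relevant correlation" level.
    measure : {"spearman", "kendall", "su"}
        Pairwise association measure used for network construction.
    abs_weights : bool
        If true (default) correlations enter the network as magnitudes, so
        strong anti-correlation also yields an edge; influence networks are
        sign-agnostic.
    inclusive_threshold : bool
        If true thresholds compare with ``>=`` instead of the default
        strict ``>``.
    n_bins : int | None
        Bin count for the symmetric-uncertainty discretization; ``None``
        selects Sturges' rule from the sample count.
    """

    th_alpha: float = 0.5
    th_beta: float = 0.7
    measure: str = "spearman"
    abs_weights: bool = True
    inclusive_threshold: bool = False
    n_bins: int | None = None

    def __post_init__(self) -> None:
        for name in ("th_alpha", "th_beta"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        if self.measure not in MEASURES:
            raise ConfigError(
                f"measure must be one of {MEASURES}, got {self.measure!r}")
        if self.n_bins is not None and self.n_bins < 2:
            raise ConfigError(f"n_bins must be >= 2, got {self.n_bins!r}")

    def exceeds(self, value: float, threshold: float) -> bool:
        """Threshold comparison under the configured convention."""
        return value >= threshold if self.inclusive_threshold else value > threshold


# ---------------------------------------------------------------------------
# the network container
# ---------------------------------------------------------------------------

class WeightedNetwork:
    """Simple undirected graph over gene identifiers with weights in [0, 1].

    Backed by a :class:`networkx.Graph`; the wrapper enforces the domain
    invariants (no self-loops, one weight per unordered pair, finite weights
    in ``[0, 1]``) and exposes a canonical edge view.
    """

    __slots__ = ("_g",)

    def __init__(self, nodes: Iterable[str] = (),
                 edges: Mapping[tuple[str, str], float] | None = None) -> None:
        self._g = nx.Graph()
        for n in nodes:
            self.add_node(n)
        if edges:
            for (a, b), w in edges.items():
                self.add_edge(a, b, w)

    # -- construction -------------------------------------------------------

    def add_node(self, name: str) -> None:
        self._g.add_node(str(name))

    def add_edge(self, a: str, b: str, weight: float) -> None:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        w = float(weight)
        if not math.isfinite(w) or not (0.0 <= w <= 1.0):
            raise ValueError(f"weight must be finite and in [0, 1], got {w!r}")
        self._g.add_edge(a, b, weight=w)

    def copy(self) -> "WeightedNetwork":
        out = WeightedNetwork()
        out._g = self._g.copy()
        return out

    # -- views --------------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edge_weights(self) -> dict[tuple[str, str], float]:
        """Edges keyed by canonical pair."""
        return {canonical_pair(a, b): d["weight"]
                for a, b, d in self._g.edges(data=True)}

    def iter_edges(self) -> Iterator[EdgeRecord]:
        for a, b, d in self._g.edges(data=True):
            x, y = canonical_pair(a, b)
            yield EdgeRecord(x, y, d["weight"])

    def sorted_edges(self) -> list[EdgeRecord]:
        return sorted(self.iter_edges(), key=lambda e: e.pair)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, name: str) -> bool:
        return self._g.has_node(name)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def weight(self, a: str, b: str) -> float:
        return self._g.edges[a, b]["weight"]

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    def neighbors(self, node: str) -> set[str]:
        return set(self._g.neighbors(node))

    def to_networkx(self) -> nx.Graph:
        """A defensive copy of the underlying graph (weights on ``weight``)."""
        return self._g.copy()

    @classmethod
    def from_networkx(cls, g: nx.Graph, default_weight: float = 1.0) -> "WeightedNetwork":
        net = cls(nodes=(str(n) for n in g.nodes))
        for a, b, d in g.edges(data=True):
            net.add_edge(str(a), str(b), d.get("weight", default_weight))
        return net

    # -- equality / repr ----------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edge_weights == other.edge_weights

    def __hash__(self):  # mutable container
        raise TypeError("WeightedNetwork is not hashable")

    def __repr__(self) -> str:
        return f"WeightedNetwork(|V|={self.n_nodes}, |E|={self.n_edges})"


# ---------------------------------------------------------------------------
# edge-list I/O
# ---------------------------------------------------------------------------

def _split_row(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _nodes_sidecar(path: Path) -> Path:
    return Path(str(path) + ".nodes")


def read_edge_list(path: str | Path, default_weight: float = 1.0) -> WeightedNetwork:
    """Read a 2- or 3-column (gene_a, gene_b[, weight]) TSV/CSV edge list.

    A header row is auto-detected by a non-numeric third field.  Unweighted
    rows receive ``default_weight``.  A duplicate unordered pair with the
    same weight is collapsed; with conflicting weights it is an error, since
    a coexpression measure assigns exactly one value per gene pair.  If a
    sidecar ``<path>.nodes`` roster exists its nodes (possibly isolated) are
    added to the network.
    """
    path = Path(path)
    net = WeightedNetwork()
    seen: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            row = _split_row(line)
            if len(row) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, "
                                 f"got {len(row)}")
            if lineno == 1 and len(row) == 3 and not _is_number(row[2]):
                continue  # header
            a, b = row[0], row[1]
            if a == b:
                raise ParseError(f"{path}:{lineno}: self-loop on {a!r}")
            if len(row) == 3:
                if not _is_number(row[2]):
                    raise ParseError(f"{path}:{lineno}: non-numeric weight "
                                     f"{row[2]!r}")
                w = float(row[2])
            else:
                w = float(default_weight)
            if not math.isfinite(w) or not (0.0 <= w <= 1.0):
                raise ParseError(f"{path}:{lineno}: weight {w} outside [0, 1]")
            pair = canonical_pair(a, b)
            if pair in seen and seen[pair] != w:
                raise ParseError(f"{path}:{lineno}: duplicate pair {pair} "
                                 f"with conflicting weights {seen[pair]} != {w}")
            seen[pair] = w
            net.add_edge(a, b, w)
    sidecar = _nodes_sidecar(path)
    if sidecar.exists():
        for raw in sidecar.read_text().splitlines():
            name = raw.strip()
            if name:
                net.add_node(name)
    return net


def write_edge_list(net: WeightedNetwork, path: str | Path) -> None:
    """Write a deterministic TSV edge list plus a ``<path>.nodes`` roster.

    Edges are sorted by canonical pair; weights are printed with
    :data:`WEIGHT_DECIMALS` decimals.  The sidecar roster preserves isolated
    nodes so ``read_edge_list(write_edge_list(net))`` reproduces ``net``
    exactly (for weights representable at that precision).
    """
    path = Path(path)
    with path.open("w") as fh:
        for e in net.sorted_edges():
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.weight:.{WEIGHT_DECIMALS}f}\n")
    with _nodes_sidecar(path).open("w") as fh:
        for n in sorted(net.nodes):
            fh.write(n + "\n")


# ---------------------------------------------------------------------------
# SIF / GraphML
# ---------------------------------------------------------------------------

def read_sif(path: str | Path, default_weight: float = 1.0) -> WeightedNetwork:
    """Read a Cytoscape simple-interaction-format file.

    Lines are ``nodeA relation nodeB [nodeC ...]``; a line with a single
    token declares an isolated node.  SIF carries no weights, so every edge
    receives ``default_weight``.
    """
    path = Path(path)
    net = WeightedNetwork()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            toks = [t for t in (t.strip() for t in toks) if t]
            if len(toks) == 1:
                net.add_node(toks[0])
            elif len(toks) >= 3:
                src = toks[0]
                for tgt in toks[2:]:
                    if tgt == src:
                        raise ParseError(f"{path}:{lineno}: self-loop on {src!r}")
                    net.add_edge(src, tgt, default_weight)
            else:
                raise ParseError(f"{path}:{lineno}: malformed SIF line "
                                 f"({len(toks)} tokens)")
    return net


def write_graphml(net: WeightedNetwork, path: str | Path) -> None:
    """Write GraphML with edge weights on the ``weight`` attribute."""
    nx.write_graphml(net.to_networkx(), str(path))


def read_graphml(path: str | Path) -> WeightedNetwork:
    return WeightedNetwork.from_networkx(nx.read_graphml(str(path)))
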