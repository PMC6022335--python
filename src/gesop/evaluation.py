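"""Gold-standard evaluation: confusion counts, precision and recall.

A network is compared to a reference interactome (YeastNet-, HumanNet- or
GeneMANIA-style edge list, presence/absence only).  Over a declared pair
universe:

* **TP** — pair edged in both networks;
* **FP** — edged in the input network only;
* **FN** — edged in the gold standard only;
* **TN** — edged in neither (quadratic in the gene count, so computed only
  on request; no reported quality measure needs it).

``precision = TP/(TP+FP)``, ``recall = TP/(TP+FN)``; both default to 0 on
an empty denominator.

The default *shared-genes* universe restricts both networks to their common
genes before counting — reference databases never cover every probe on an
array, and pairs they cannot speak to should not count as false positives.
An *all-input-pairs* mode (universe = every pair over the input network's
nodes) is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .netcore import EvaluationError, WeightedNetwork

logger = logging.getLogger("gesop.evaluation")

UNIVERSE_MODES = ("shared", "all-input")


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN for one network vs a gold standard.

    ``tn`` is ``None`` unless requested.  ``excluded_net_edges`` /
    ``excluded_gold_edges`` count edges dropped because an endpoint falls
    outside the pair universe.
    """

    tp: int
    fp: int
    fn: int
    tn: int | None
    universe: str
    n_universe: int
    excluded_net_edges: int = 0
    excluded_gold_edges: int = 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "universe": self.universe, "n_universe": self.n_universe,
            "excluded_net_edges": self.excluded_net_edges,
            "excluded_gold_edges": self.excluded_gold_edges,
        }


@dataclass
class QualityScores:
    precision: float
    recall: float

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall}


def confusion_counts(net: WeightedNetwork, gold: WeightedNetwork,
                     universe: str = "shared",
                     compute_tn: bool = False) -> ConfusionCounts:
    """Count TP/FP/FN (and optionally TN) of ``net`` against ``gold``.

    ``gold`` weights are ignored; an edge is an edge.  Raises
    :class:`EvaluationError` when the universe holds fewer than two genes.
    """
    if universe not in UNIVERSE_MODES:
        raise ValueError(f"universe must be one of {UNIVERSE_MODES}")
    if universe == "shared":
        genes = net.nodes & gold.nodes
    else:
        genes = net.nodes
    if len(genes) < 2:
        raise EvaluationError(
            f"pair universe has {len(genes)} gene(s); need at least 2")

    net_edges = set(net.edge_weights)
    gold_edges = set(gold.edge_weights)
    net_in = {p for p in net_edges if p[0] in genes and p[1] in genes}
    gold_in = {p for p in gold_edges if p[0] in genes and p[1] in genes}
    excluded_net = len(net_edges) - len(net_in)
    excluded_gold = len(gold_edges) - len(gold_in)
    if excluded_net or excluded_gold:
        logger.info("confusion_counts: excluded %d network and %d gold edges "
                    "outside the %s universe", excluded_net, excluded_gold,
                    universe)

    tp = len(net_in & gold_in)
    fp = len(net_in - gold_in)
    fn = len(gold_in - net_in)
    n_universe = len(genes) * (len(genes) - 1) // 2
    tn = n_universe - tp - fp - fn if compute_tn else None
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, universe=universe,
                           n_universe=n_universe,
                           excluded_net_edges=excluded_net,
                           excluded_gold_edges=excluded_gold)


def precision(c: ConfusionCounts) -> float:
    """``TP / (TP + FP)``; 0 by convention when the network has no edges."""
    denom = c.tp + c.fp
    if denom == 0:
        logger.info("precision: TP+FP == 0, returning 0 by convention")
        return 0.0
    return c.tp / denom


def recall(c: ConfusionCounts) -> float:
    """``TP / (TP + FN)``; 0 by convention when the gold standard is empty."""
    denom = c.tp + c.fn
    if denom == 0:
        logger.info("recall: TP+FN == 0, returning 0 by convention")
        return 0.0
    return c.tp / denom


def quality_scores(c: ConfusionCounts) -> QualityScores:
    return QualityScores(precision=precision(c), recall=recall(c))
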