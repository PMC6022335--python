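"""Coexpression-network construction from an expression matrix.

Three association measures are supported, all standard in information-based
network inference:

* **Spearman's rho** — rank correlation, average ranks for ties;
* **Kendall's tau** — tau-b, the tie-corrected variant (microarray data is
  quantized, so ties happen);
* **Symmetric uncertainty (SU)** — ``2·I(X;Y)/(H(X)+H(Y))``, a normalized
  mutual information in [0, 1], computed by plug-in entropies on
  equal-frequency-binned values.

An edge is created for every gene pair whose (optionally magnitude-
transformed) measure exceeds the construction cut-off ``th_alpha``.  A
permissive cut-off such as the default 0.5 deliberately yields an
over-connected network — the intended input of the optimizer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .netcore import (GesopConfig, UndefinedMeasureError, WeightedNetwork,
                      canonical_pair)

logger = logging.getLogger("gesop.inference")


# ---------------------------------------------------------------------------
# expression container
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with identifiers.

    Missing values are represented as NaN; pairwise computations use
    complete observations only.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(gene_ids=[str(i) for i in df.index],
                   sample_ids=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a genes × samples table (first column = gene identifiers)."""
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return cls.from_frame(df)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")


@dataclass
class MeasureResult:
    """Raw measure value and the [0, 1] edge weight derived from it."""

    pair: tuple[str, str]
    raw: float
    weight: float


# ---------------------------------------------------------------------------
# pairwise measures
# ---------------------------------------------------------------------------

def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises :class:`UndefinedMeasureError` for constant vectors or fewer
    than 3 complete observations.
    """
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise UndefinedMeasureError(
            f"need >= 3 complete observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMeasureError("correlation undefined for constant vector")
    rho = stats.spearmanr(x, y).statistic
    if not math.isfinite(rho):
        raise UndefinedMeasureError("spearman correlation undefined")
    return float(rho)


def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation."""
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise UndefinedMeasureError(
            f"need >= 3 complete observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMeasureError("correlation undefined for constant vector")
    tau = stats.kendalltau(x, y).statistic
    if not math.isfinite(tau):
        raise UndefinedMeasureError("kendall correlation undefined")
    return float(tau)


def sturges_bins(n_samples: int) -> int:
    """Sturges' rule, ``ceil(log2(n) + 1)`` — robust for short series."""
    return max(2, math.ceil(math.log2(max(n_samples, 2)) + 1))


def _equal_frequency_bins(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into (up to) n_bins equal-frequency bins; returns labels."""
    qs = np.quantile(v, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, v, side="left")


def symmetric_uncertainty(x, y, n_bins: int | None = None) -> float:
    """Symmetric uncertainty ``2·I(X;Y) / (H(X) + H(Y))`` in [0, 1].

    Values are discretized into equal-frequency bins (Sturges' count by
    default) and entropies are plug-in estimates on the contingency table.
    ``SU(x, x) = 1`` for any non-constant ``x``; two constant vectors have
    zero total entropy and raise :class:`UndefinedMeasureError`.
    """
    x, y = _complete_pairs(x, y)
    if x.size < 3:
        raise UndefinedMeasureError(
            f"need >= 3 complete observations, got {x.size}")
    if n_bins is None:
        n_bins = sturges_bins(x.size)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bx = _equal_frequency_bins(x, n_bins)
    by = _equal_frequency_bins(y, n_bins)
    return su_from_labels(bx, by)


def su_from_labels(bx: np.ndarray, by: np.ndarray) -> float:
    """SU on already-discretized label vectors (plug-in entropies)."""
    n = bx.size
    joint = pd.crosstab(pd.Series(bx), pd.Series(by)).to_numpy() / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    hx = stats.entropy(px, base=2)
    hy = stats.entropy(py, base=2)
    hxy = stats.entropy(joint.ravel(), base=2)
    if hx + hy == 0.0:
        raise UndefinedMeasureError("both vectors constant: zero total entropy")
    mi = hx + hy - hxy
    su = 2.0 * mi / (hx + hy)
    # plug-in arithmetic can stray a hair outside [0, 1]
    return float(min(1.0, max(0.0, su)))


_MEASURE_FUNCS = {
    "spearman": lambda x, y, cfg: spearman_rho(x, y),
    "kendall": lambda x, y, cfg: kendall_tau(x, y),
    "su": lambda x, y, cfg: symmetric_uncertainty(x, y, cfg.n_bins),
}


def pair_measure(x, y, cfg: GesopConfig) -> MeasureResult:
    """Raw measure and [0, 1] edge weight for one gene pair under ``cfg``."""
    raw = _MEASURE_FUNCS[cfg.measure](x, y, cfg)
    if cfg.measure == "su":
        weight = raw
    else:
        weight = abs(raw) if cfg.abs_weights else max(raw, 0.0)
    return MeasureResult(pair=("", ""), raw=raw, weight=weight)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class InferenceStats:
    pairs_evaluated: int = 0
    pairs_kept: int = 0
    pairs_skipped: int = 0


def infer_network(expr: ExpressionMatrix, cfg: GesopConfig,
                  stats_out: InferenceStats | None = None) -> WeightedNetwork:
    """Build the coexpression network: one node per gene, an edge for every
    pair whose weight exceeds ``cfg.th_alpha``.

    Pairs where the measure is undefined (constant rows, too few complete
    observations) are skipped; the skip count is logged and available via
    ``stats_out``.
    """
    st = stats_out if stats_out is not None else InferenceStats()
    net = WeightedNetwork(nodes=expr.gene_ids)
    genes = expr.gene_ids
    vals = expr.values
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            st.pairs_evaluated += 1
            try:
                res = pair_measure(vals[i], vals[j], cfg)
            except UndefinedMeasureError:
                st.pairs_skipped += 1
                continue
            if cfg.exceeds(res.weight, cfg.th_alpha):
                a, b = canonical_pair(genes[i], genes[j])
                net.add_edge(a, b, min(res.weight, 1.0))
                st.pairs_kept += 1
    logger.info("infer_network: %d pairs evaluated, %d kept, %d skipped "
                "(measure=%s, th_alpha=%s)", st.pairs_evaluated, st.pairs_kept,
                st.pairs_skipped, cfg.measure, cfg.th_alpha)
    if net.n_edges == 0:
        logger.warning("infer_network produced an empty edge set")
    return net
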