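"""Published benchmark confusion counts for the GeSOp evaluation study.

The original evaluation of GeSOp scored three coexpression networks per
organism (built with Kendall, Spearman and symmetric-uncertainty measures
at a 0.5 construction cut-off) against public interactome gold standards,
reporting TP/FP counts and two-decimal precision for the raw *input*
network, the Step-1 *pruned* forest, and the final *gesop* network.

These counts are inputs, not results: they let the precision/recall
arithmetic of :mod:`gesop.evaluation` be validated against independently
reported numbers without access to the original multi-gigabyte data.  The
reported precisions mix rounding and truncation, so agreement is expected
at the printed number of decimals, within one hundredth.
"""

from __future__ import annotations

from typing import NamedTuple


class BenchmarkCell(NamedTuple):
    organism: str       # "yeast" | "human"
    gold: str           # reference interactome
    measure: str        # construction measure
    stage: str          # "input" | "pruned" | "gesop"
    tp: int
    fp: int
    printed_precision: float
    printed_decimals: int


def _cells(organism, gold, rows):
    out = []
    for measure, triples in rows.items():
        for stage, (tp, fp, prec) in zip(("input", "pruned", "gesop"), triples):
            dec = max(len(str(prec).split(".")[1]), 1) if "." in str(prec) else 0
            out.append(BenchmarkCell(organism, gold, measure, stage,
                                     tp, fp, prec, dec))
    return out


#: all published TP/FP/precision cells, keyed implicitly by
#: (organism, gold standard, measure, pipeline stage)
BENCHMARK_CELLS: list[BenchmarkCell] = (
    _cells("yeast", "yeastnet", {
        "kendall": [(8331, 444362, 0.01), (94, 4035, 0.02), (909, 9449, 0.094)],
        "spearman": [(19706, 1864316, 0.01), (64, 4374, 0.01), (6589, 328473, 0.02)],
        "su": [(1744, 102890, 0.01), (94, 3496, 0.026), (436, 20850, 0.02)],
    })
    + _cells("yeast", "genemania", {
        "kendall": [(194918, 400383, 0.32), (1942, 3273, 0.37), (7863, 8423, 0.48)],
        "spearman": [(692753, 1770378, 0.28), (1909, 3326, 0.36), (147360, 293279, 0.33)],
        "su": [(43991, 95244, 0.31), (1722, 2824, 0.37), (10281, 18206, 0.36)],
    })
    + _cells("human", "genemania", {
        "kendall": [(17144, 26416, 0.39), (1282, 2759, 0.31), (2085, 3116, 0.4)],
        "spearman": [(351686, 2512234, 0.12), (1305, 11646, 0.10), (52563, 248969, 0.18)],
        "su": [(525, 745, 0.40), (299, 545, 0.35), (303, 553, 0.36)],
    })
    + _cells("human", "humannet", {
        "kendall": [(4216, 35931, 0.10), (276, 3291, 0.07), (586, 4084, 0.12)],
        "spearman": [(46850, 2465035, 0.01), (141, 10540, 0.01), (8202, 258413, 0.03)],
        "su": [(125, 1045, 0.10), (77, 699, 0.09), (77, 711, 0.09)],
    })
)


#: published network sizes (nodes, input edges, final edges) per measure
PUBLISHED_SIZES = {
    ("yeast", "kendall"): (5466, 619552, 10801),
    ("yeast", "spearman"): (5521, 2555009, 446704),
    ("yeast", "su"): (4802, 145329, 26421),
    ("human", "kendall"): (8068, 68329, 9783),
    ("human", "spearman"): (31061, 5387473, 567590),
    ("human", "su"): (1431, 1871, 1121),
}
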