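# Methods

## The problem

Coexpression gene networks built by thresholding a pairwise association
measure at a permissive cut-off are *over-connected*: they contain hundreds
of thousands to millions of edges, most of them spurious, which destroys
both their readability and their scale-free character. This package
implements a structure optimizer (GeSOp) that prunes such a network down to
its most relevant relationships while preserving every gene, together with
the surrounding workflow: network construction, gold-standard evaluation,
and topology diagnostics.

## The optimizer

**Step 1 — maximum-relevance spanning forest.** Edges are sorted by weight
descending (canonical lexicographic pair order breaks ties) and accepted
greedily iff they join two distinct components, tracked with a union–find
structure — Kruskal's algorithm with reversed ordering. The standard
cut/exchange argument makes the greedy forest optimal: its total weight is
the maximum over all spanning forests. Guarantees: the forest spans every
node of the input (node conservation), contains exactly |V| − C edges
(C = number of connected components), and is acyclic. Both properties are
verified in the test suite by exhaustive enumeration of spanning trees on
small graphs and against an independent library implementation.

**Step 2 — hub-aware re-addition.** Hubs are the nodes of the forest whose
degree strictly exceeds the forest's mean degree 2|E|/|V|. The mean runs
over *all* nodes, isolated ones included, because average connectivity is a
whole-network quantity. Every pruned edge with at least one hub endpoint
and weight above `th_beta` is restored (once, even if both endpoints are
hubs). Hubs are identified once on the forest and not recomputed as edges
return: re-addition is then a single deterministic pass, whereas iterative
recomputation has no clearly terminating rule. Removed edges are indexed by
endpoint, so Step 2 is linear in the number of pruned edges.

The composition never invents a relationship (output edges ⊆ input edges)
and conserves the node set. Output edge count lies in [|V| − C, |E|] and is
non-increasing in `th_beta`.

## Construction measures

* **Spearman's rho** and **Kendall's tau-b** (tie-corrected; microarray
  data is quantized, so ties occur), via scipy. Average ranks for ties.
* **Symmetric uncertainty** SU = 2·I(X;Y)/(H(X)+H(Y)) ∈ [0, 1], plug-in
  entropies on equal-frequency bins. The bin count defaults to Sturges'
  rule ⌈log₂(n)+1⌉ — robust for short expression series. SU(x, x) = 1 for
  non-constant x; two constant vectors have zero total entropy and the
  measure is reported undefined.

Correlations enter the network as magnitudes by default (`abs_weights`):
influence networks are sign-agnostic, and strong anti-correlation is as
informative as correlation. A flag restricts edges to positive raw values.

Thresholds compare strictly (`>`) by default — an edge must *exceed* the
cut-off — with an `inclusive_threshold` flag for `≥`, since both
conventions appear in practice. Missing values use pairwise-complete
observations; a pair with fewer than 3 complete observations, or with a
constant vector, yields no edge and is counted in the log.

### Defaults

| parameter | default | meaning |
|---|---|---|
| `th_alpha` | 0.5 | construction cut-off; deliberately low, produces the over-connected input the optimizer targets |
| `th_beta` | 0.7 | re-addition cut-off; the conventional "relevant correlation" level |
| `measure` | spearman | least restrictive of the three; kendall and su available |
| `n_bins` | Sturges | SU discretization |

## Evaluation

Confusion counts against a gold-standard interactome use, by default, the
*shared-genes* pair universe: all unordered pairs over the intersection of
the two node sets. Edges with an endpoint outside the shared set are
excluded and counted, not treated as false positives — a reference database
cannot falsify a relationship between genes it does not cover. An
`all-input` universe (pairs over the input network's nodes) is available
for sensitivity analysis. TN is quadratic in the gene count and is computed
only on request; precision TP/(TP+FP) and recall TP/(TP+FN) never need it.
Both scores default to 0 on an empty denominator. Gold-standard confidence
scores are ignored; presence/absence only.

The package embeds the published benchmark TP/FP counts of the method's
original evaluation (yeast cell-cycle and human SNP coexpression networks
against YeastNet, GeneMANIA and HumanNet) as *inputs*: the acceptance
script and tests recompute precision from them and compare against the
reported two-decimal values at their printed precision, within one
hundredth, since the reported values mix rounding and truncation (one
human/GeneMANIA cell prints 0.40 where the counts give 0.413).

## Topology indicators

Clustering coefficient (mean local coefficient, degree-<2 nodes contribute
0), characteristic path length and diameter (unweighted shortest paths
over *connected* pairs; disconnected pairs are excluded and counted, so the
indicators stay defined after aggressive pruning — the behaviour of the
usual desktop network analyzers), and density 2|E|/(|V|(|V|−1)).

The power-law exponent γ of the degree distribution is, by default, the
magnitude of the least-squares slope of log P(k) vs log k over the
observed positive degrees — the classic log-log regression, matching the
tooling this style of analysis conventionally uses — not a Clauset-style
MLE. A continuous ML estimate (1 + n/Σ ln(k/(k_min−½))) is exposed as an
alternative; it is accurate for k_min ≳ 6 and is not used by default.
Fewer than 3 distinct positive degrees (e.g. any regular graph) leaves γ
undefined; undefined indicators are reported as null, never silently
zeroed. Degree-0 nodes are excluded from the γ fit but included in density
and mean degree.

## Synthetic data

The generators stand in for the multi-gigabyte microarray datasets and
interactome downloads of a real study; all are pure functions of a
`SynthSpec` (seed included).

* `generate_scale_free` — preferential-attachment graph, i.i.d.
  Uniform(0.5, 1) weights. Edge count is exactly `attach_m·(n −
  attach_m)`.
* `generate_overconnected` — a scale-free *backbone* with weights in
  (0.7, 1] plus `extra_edge_frac · |E_backbone|` uniformly random spurious
  edges with weights in (0.5, 0.7). The backbone is returned as the
  planted truth. Every backbone edge outweighs every spurious edge, so the
  conventional `th_beta = 0.7` separates signal from noise by
  construction, making planted-recovery results sharp and interpretable.
* `generate_expression` — genes assigned round-robin to modules; gene g in
  module m is `latent_m + noise_sd·ε`, latents standard normal per sample.
  Within-module Pearson correlation concentrates at 1/(1+noise_sd²);
  `noise_sd` defaults to the value that hits `within_module_corr`.

**Study conditions.** Defaults are `n_genes = 500`, `attach_m = 1`,
`extra_edge_frac = 5`, `n_samples = 30`, `n_modules = 5`,
`within_module_corr = 0.8`. The backbone is grown with one attachment per
gene — a scale-free tree — because the relevant-signal skeleton of a large
coexpression network, once pruned, is near-forest (optimized edge counts
on real networks sit near the node count). The 5× dilution makes ~83% of
input edges spurious, inside the 82–98% reduction range over-connected
coexpression networks exhibit, and dense enough that the input's
clustering, density and degree distribution are dominated by the random
dilution while the output's are dominated by the scale-free backbone — the
regime the optimizer is designed for.

**What the generators do not emulate:** correlation-transitivity of real
coexpression graphs (spurious edges here are independent uniform pairs,
whereas thresholded correlation matrices are locally dense), heavy-tailed
microarray noise, probe-level redundancy, and missing values. Passing the
synthetic experiments therefore demonstrates the optimizer's structural
behaviour (what it keeps, what it prunes, how topology shifts), not
biological fidelity on any particular real dataset.

**Real-data preprocessing caveat.** For public microarray series (e.g. the
yeast cell-cycle cdc15 experiment), published network sizes depend on
unreported preprocessing choices — log transformation, missing-value
handling, probe filtering. Reproductions on such data should document
their own preprocessing and expect edge-count divergence; the package
deliberately validates its arithmetic against published confusion counts
rather than claiming end-to-end reproduction of those networks.

## Numerical choices

* Canonical unordered pair = lexicographic order; all serialization is
  sorted, so identical input + config ⇒ byte-identical output.
* Edge weights serialize with 6 decimals; generators round weights to 6
  decimals at creation so write→read round trips are exact.
* Duplicate pair with conflicting weights in an input file is an error
  (one measure value per pair), equal weights collapse.
* Equal-weight edges in Step 1 are taken in canonical-pair order —
  reproducible across platforms; with distinct weights the maximum forest
  is unique and tie-breaking is moot.
* Plug-in SU is clipped to [0, 1] against floating-point stray.
* Empty networks: forest of an edgeless network is itself; CPL/diameter/γ
  are undefined (null), not 0.

## Problem sizes

Desk-scale experiment sizes used by the test suite and the acceptance
script — 500-gene networks with ~3,000 edges, 20 seeds for directional
topology comparisons, 10 seeds for planted-precision, 100–200 exhaustively
checked small graphs (≤ 8 nodes) for forest optimality — were chosen so
the full battery completes in a few minutes while leaving each effect far
from its decision boundary (e.g. planted precision moves from 1/6 to 1.0).

## Known limitations

* Step 2 with hubs recomputed iteratively is not implemented (no
  terminating rule); a single-pass convention is documented above.
* The log-log γ fit is biased on hump-shaped (Poisson-like) degree
  distributions; it is reported because it is the conventional indicator
  in this analysis style, with the MLE as the principled alternative.
* Directed networks, multi-edges, confidence-weighted gold standards and
  p-value-based construction are out of scope.
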