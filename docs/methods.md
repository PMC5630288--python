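# Methods

`mirnet` implements a network-biology workflow for interpreting a
differential-expression (DE) experiment — typically an RNAseq contrast such
as miRNA inhibition versus control — through the lens of known functional
gene/protein interactions. The workflow has five stages: consolidated
interactome assembly, DEG selection, subnetwork induction with
largest-connected-component (LCC) extraction, spectral module detection,
and hypergeometric over-representation analysis (ORA) with FDR control.
This note records the models, the assumptions, the defaults and why, and
the design choices made where the design was genuinely open.

## Consolidated interactome

Interaction catalogues (BioGRID, CORUM, DIP, InnateDB, IntAct, MatrixDB,
MINT, ...) report overlapping content in different dialects. `mirnet`
parses a plain two-symbol edge list and a simplified PSI-MITAB layout
(interactor symbols taken from the alias columns; only that minimal subset
of PSI-MITAB 2.5 is honoured) and merges everything into one undirected
gene-symbol graph, the *consolidated interactome* (CI):

* **Identifier namespace.** Plain uppercased gene symbols. Case-folding is
  what makes a mouse DE gene list (`Pdcd4`) land on a human interactome
  node (`PDCD4`); it is a symbol-level approximation of orthology, not an
  ortholog map, and will mis-join the minority of genes whose mouse and
  human symbols differ. Placeholder identifiers (`-`, `NA`, empty) are
  treated as unusable and their records dropped.
* **Edge semantics.** All interactions are undirected, untyped and
  unweighted: the sources mix transcriptional, translational and
  protein-level relations with no consistent direction or confidence
  scale, so none is invented. Duplicate and reversed records collapse to
  one edge whose *provenance* — the set of contributing source labels — is
  retained and exported; the free-text interaction type tag survives only
  in the provenance export.
* **Self-loops** are removed; a record set whose surviving edge set is
  empty is a fatal input error, while individual malformed lines are
  skipped and counted.

The builder is idempotent: rebuilding from the CI's own exported edge list
reproduces the identical graph, which the tests assert.

## DEG selection

A DE results table supplies, per gene, a log2 fold change and an
unadjusted p-value (the upstream DE fit — e.g. a DESeq2 negative-binomial
model — is out of scope; its output table is the contract). A gene is
called differentially expressed when it passes **both** cutoffs strictly:

    up:   log2fc >  log2(fc_threshold)  and  p < p_threshold
    down: log2fc < -log2(fc_threshold)  and  p < p_threshold

`fc_threshold` is a *linear* fold change applied symmetrically (default
1.5; a laxer 1.25 is a configuration away — both conventions circulate for
this kind of contrast and the package takes no position on which is
"right"). `p_threshold` defaults to 0.05 on the unadjusted p-value.
Duplicate symbols in the input resolve to the row with the smallest
p-value. Tightening either cutoff can only shrink the selection
(monotonicity), and up/down are disjoint by construction; both are
property-tested.

## Subnetwork and LCC

The DEG subnetwork is the CI subgraph induced on the DEG list: exactly the
CI edges with **both** endpoints differentially expressed. DEGs that sit
in the CI but have no DEG neighbour contribute no edge; they are excluded
from the graph and reported separately in the run summary, so both
conventions' node counts are visible. The LCC is the connected component
with the most nodes; ties (rare outside toy graphs) go to the component
containing the lexicographically smallest symbol, making the result
order-independent.

## Spectral module detection

Modules — densely connected subsets of the LCC — are found by recursive
two-way spectral bisection, exposed as the scikit-learn-compatible
clusterer `SpectralGraphPartitioner` (precomputed-adjacency `fit`,
`labels_`, `modularity_`):

1. For the current node set, compute the **Fiedler vector**: the
   eigenvector of the second-smallest eigenvalue of the symmetric
   normalized Laplacian `L = I − D^{−1/2} A D^{−1/2}`.
2. Split by sign of the Fiedler entries; zero entries join the positive
   side. The eigenvector's global sign is fixed so that its first nonzero
   entry in node-sorted order is positive, removing the eigensolver's sign
   ambiguity.
3. **Fine-tune** the candidate split by greedy single-node moves between
   the two halves, in deterministic index order, accepting a move only
   when total Newman modularity strictly increases and both halves keep
   the size floor. This is the standard refinement stage of
   bisection-based modularity methods; without it an early cut that lands
   inside a dense region strands nodes on the wrong side and recursion
   cannot repair them.
4. Accept the split only if it strictly increases total **Newman
   modularity** `Q = Σ_c [e_c/m − (d_c/2m)²]` (intra-module edge fraction
   minus its degree-preserving null expectation) *and* both sides have at
   least `min_module_size` nodes (default 5). Recurse on accepted sides.

Recursive bisection with a modularity stopping rule avoids choosing the
number of modules up front (the reason k-way spectral clustering was not
used). Module ids are relabelled contiguously from 0 in order of each
module's smallest node.

Numerical choices: subgraphs of ≤ 1500 nodes use a dense symmetric
eigensolver (exact, deterministic); larger ones use shift-inverted Lanczos
with a start vector drawn from the seeded generator, so the whole
procedure is deterministic for a fixed seed. Modularity gains are compared
against a 1e-12 floor to keep float noise from flipping accept/reject
decisions. An eigensolver failure on a subgraph demotes that subgraph to a
terminal module with a logged warning rather than aborting the run.
Degree-zero rows (possible only on degenerate inputs, not on an LCC) get a
zero in `D^{−1/2}`.

On planted-partition benchmarks (stochastic block model, 4 blocks × 50
nodes, within-block edge probability 0.30, between-block 0.01) the
partitioner recovers the planted modules with adjusted Rand index ≥ 0.9 in
at least 9 of 10 seeds, and recovery degrades monotonically as the
between-block probability approaches the within-block one — both asserted
in the tests.

## miRNA-target overlay

Predicted-target lists from any number of prediction algorithms
(TargetScan, PicTar, Diana-microT, ...) are intersected with the network
nodes. A node is flagged as a predicted target when at least
`vote_threshold` algorithms list it; the default is 1, i.e. the union,
with per-algorithm sets retained for reporting. The GraphML export carries
`direction` (up/down), `module` and `predicted_target` node attributes —
the conventional red/green fill and thick-border display semantics.

## Over-representation analysis

For a foreground of `n` genes inside a universe of `N`, and a term
annotating `K` universe genes of which `k` are in the foreground, the
enrichment p-value is the upper hypergeometric tail

    p = P(X ≥ k),  X ~ Hypergeometric(N, K, n),

evaluated through the log-gamma-based survival function (never naive
factorials), with `GeneRatio = k/n` and `BgRatio = K/N` reported alongside.
Terms are intersected with the universe first and tested only when
`K ∈ [min_set, max_set]` (defaults 10 and 500, the conventional ORA window
that drops uninformatively small and broad terms). The universe defaults
to every gene in the DE table — the set of genes the experiment could have
called — and is configurable.

Across all tested terms, p-values receive Benjamini–Hochberg step-up
adjustment (`p.adjust`) and Storey q-values `q_i = π̂0 · p.adjust_i` with
the single-λ null-proportion estimate `π̂0 = min(1, mean(p > 0.5)/0.5)`,
falling back to `π̂0 = 1` below 10 p-values where the estimator is too
unstable. The single-λ rule was chosen over the spline-over-λ-grid variant
for determinism and simplicity; q-values therefore differ slightly from
spline-based implementations, dominate nothing (q ≤ p.adjust always) and
are monotone in p-rank. Exported tables render probabilities with 3
significant digits and an uppercase E (`5.21E-20`).

Per-module enrichment runs the same test with each module's gene set as
foreground against the unchanged universe — the natural companion to
labelled network displays — in addition to the global DEG-list enrichment.

## Synthetic data and what passing tests mean

`SyntheticSpec` generates every input format the pipeline reads, with
ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 20,949 | universe size (mirrors a ~20,949-gene DE table) |
| `blocks` | 4 × 50 | planted interactome modules (SBM blocks) |
| `p_in` / `p_out` | 0.30 / 0.01 | within/between-block edge probability |
| `deg_fraction` | 0.19 | DE fraction (mirrors a ~4,009-gene foreground) |
| `lfc_effect` / `lfc_noise` | 2.0 / 0.3 | mean |log2fc| of true DEGs / null spread |
| `planted_terms` | (100,×5), (100,×4), (50,×5) | enriched gene sets (size, fold) |
| `target_fraction` | 0.3 | per-algorithm predicted-target sampling rate |
| `n_background_terms` | 200 | unenriched terms in the GMT |

True DEGs include all block genes (so the DEG subnetwork inherits the
planted modules) plus a uniform draw from the rest of the universe up to
the DE quota; signal genes get `±Normal(lfc_effect, lfc_noise)` log2 fold
changes and `Beta(0.1, 10)` p-values, null genes `Normal(0, lfc_noise)`
and `Uniform(0, 1)`. Planted terms of size `s` and fold `f` contain
`min(s, round(f · deg_fraction · s))` true DEGs. Target lists sample
network genes independently per algorithm, so list overlaps follow the
product rule.

The generator emulates the *statistical* structure the analysis assumes —
modular interaction topology, a thresholdable DE table, enriched terms —
and deliberately not the rest: real interactomes are scale-free-ish with
hubs and dense cores, not block-uniform; real DE p-values come from a
count model with dispersion shrinkage, not a Beta; real annotation terms
overlap hierarchically. Passing the planted-recovery and FDR tests
therefore demonstrates that the machinery is correct and calibrated under
its own assumptions, not that any particular biological dataset will yield
stable modules.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use: exhaustive hypergeometric
enumeration for all universes N ≤ 25; 200 random graphs (n ≤ 50) for the
LCC/union-find comparison; 10 SBM seeds at 4 × 50 nodes for module
recovery; 50 replicates of a 200-term, 20,000-gene-universe,
4,000-gene-foreground simulation for null FDR and planted-term detection;
and the full default synthetic study (20,949 genes) for end-to-end
determinism and stage-composition equality. These sizes give stable
pass/fail behaviour at interactive runtimes.

## Known limitations

* Symbol case-folding is the only cross-species mapping; paralog
  collisions and renamed symbols are not resolved.
* The CI keeps no interaction direction, sign or confidence; modules are
  purely topological.
* Fiedler bisection with greedy refinement is a local heuristic: it
  carries no recovery guarantee near the detectability threshold of weak
  planted structure, and the modularity objective itself has a resolution
  limit (modules much smaller than `√(2m)` can be absorbed).
* q-values use a single-λ π0 estimate; for small term collections the
  conservative `π̂0 = 1` fallback makes them equal BH values.
* GMT term sets are taken as given — no ontology-graph propagation.
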