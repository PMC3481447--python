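# Methods

## Model and procedure

The package assumes disease-relevant genes act as *connectors*: they need not
be differentially expressed themselves, but they lie on network paths between
genes that are. Operationally, the DE genes are terminals *R* of a Steiner
tree problem on the PPI network *G = (V, E, w)*; the genes recruited to
connect them — Steiner vertices together with terminals that are internal
(degree > 1) in the tree — are the candidate markers (STMs).

The Steiner tree problem is NP-hard, so trees are built with the shortest-path
2-approximation heuristic: repeatedly merge the two closest forest components
along a weighted shortest path, then take the MST of the induced subgraph and
prune non-terminal leaves to a fixed point. Pruning can only remove
non-terminal degree-1 vertices, so it never disconnects the tree or drops a
terminal; every leaf of the final tree is a terminal, which is why "internal
vertices" and "Steiner vertices ∪ non-leaf terminals" coincide.

A single tree is one of many near-optimal solutions. The ensemble redraws all
edge weights i.i.d. uniform on [0.99, 1.0) each iteration and reruns the
heuristic; because all weights stay within 1% of unity, the perturbation acts
as random tie-breaking among (near-)equal-hop paths rather than a change of
objective, and alternative or redundant connector paths are visited across
iterations. The STM set is the plain union of internal vertices over the
ensemble — no frequency threshold is applied, though per-gene occurrence
counts are kept as metadata.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `weight_low`, `weight_high` | 0.99, 1.0 | support of the uniform edge-weight draw (dimensionless); half-open interval — no result can depend on the measure-zero boundary |
| `max_iterations` | 500 | hard cap on ensemble size |
| `patience` | 50 | stop after this many consecutive iterations adding no new STM |
| `seed` | — | master seed; iteration *i* uses substream (seed, *i*), so early stopping never changes the genes any completed iteration contributes |

Saturation of the STM union is an empirical matter (a few hundred iterations
on networks of ~10⁴ genes); the patience rule makes the informal
"until the count converges" criterion operational and configurable.

Classification uses default-hyperparameter logistic regression
(L2, C = 1) or a linear-kernel SVM, stratified 10-fold cross-validation
repeated 100 times, and AUC computed on the pooled out-of-fold decision
scores of each repetition. Stratification is the defensible default for the
27–37% positive-class fractions typical of metastasis cohorts; pooled
(rather than per-fold-averaged) AUC was chosen for its lower variance. No
feature selection or hyperparameter tuning happens inside the classifier: the
point is to score the whole marker set, not to optimize a classifier.

## Overlap statistics

Percent overlap is the Jaccard index × 100. Significance is the one-sided
upper hypergeometric tail with background *N* = number of genes in the PPI
network's largest connected component; no two-sided option, continuity
correction, or multiple-testing adjustment is applied. The tail is summed in
log space (log-gamma binomial coefficients, log-sum-exp), because observed
values reach 1e−159 — far beyond double-precision underflow of a naive sum.
`log10_p` is the authoritative output below ~1e−15; the linear `p_value` is
clamped to the smallest positive double when it underflows. Impossible terms
(i > m or n − i > N − m) contribute zero probability; an overlap at or below
the support minimum max(0, m+n−N) has p = 1 exactly.

## Synthetic data

The generator emulates the pipeline's three real inputs at desk scale:

- **Network**: Barabási–Albert preferential attachment (default 2000 nodes,
  3 edges per new node) reproduces the heavy-tailed degree distribution of
  PPI networks. It does not reproduce their clustering coefficients, motif
  spectra, or annotation biases.
- **Planted connectors**: the highest-degree pairwise non-adjacent hubs
  (default 20). DE genes (default 100) are drawn from the connectors'
  neighborhoods, which places connectors on many shortest paths between DE
  genes — the premise the method exploits, made literal.
- **Expression**: i.i.d. Gaussian noise (default SD 1) with a +2 SD mean
  shift on DE genes in the positive class, 200 samples split evenly. Real
  microarray data have correlated noise, batch structure, and uneven class
  sizes; none of that is modelled.

Consequently, passing tests show that the algorithms recover structure they
are designed to recover under idealized conditions — they do not certify
performance on real cohorts, where signal is weaker and the network is
incomplete. The planted-connector recovery check (STM recovery vs 1000
equal-sized random draws, one-sided permutation p < 0.05 on ≥ 9 of 10 seeds)
and the classifier checks (mean AUC > 0.9 at a 2 SD effect; mean AUC within
0.5 ± 0.05 on no-signal data) are calibration tests of that kind. For the
no-signal check, a single 200-sample dataset's cross-validated AUC has a
standard deviation of roughly 0.04 from ranking noise alone, so calibration
is judged on the mean over four independent no-signal datasets, each
evaluated with the full 100×10-fold protocol, and the null feature set is
kept small (10 genes) to avoid the well-known pessimistic bias of
cross-validation with heavily overparameterized null models.

## Numerical and design choices

- **Distances while merging.** Shortest-path distances in the (fixed,
  per-iteration perturbed) host graph do not change as the forest grows, so
  the solver computes each vertex's single-source distance row once
  (batched Dijkstra on a CSR matrix) and finds the closest component pair by
  an argmin over the cached pairwise matrix. This is mathematically identical
  to recomputing component-pair distances after each merge, at a small
  fraction of the cost.
- **Tie-breaks.** Equal closest-pair distances and equal MST edge weights are
  broken by lexicographic order of the endpoint identifiers; in ensemble use
  the random weights make exact ties a measure-zero event, so the ensemble's
  diversity comes from the perturbation, not from the deterministic rule.
  Equal-length shortest *paths* between a fixed pair are resolved by the
  Dijkstra predecessor structure (deterministic for a given weight vector).
- **Degenerate inputs.** A single terminal yields a one-vertex, zero-edge
  tree with no internal vertices. Terminals in different components raise an
  error naming the offending genes; `discover_stms` first restricts to the
  largest connected component and warns about terminals dropped by that
  restriction. Self-loops in edge lists are dropped and counted, duplicate
  (including reversed) edges collapsed keeping the first weight.
- **Brute-force oracle.** Exact minimum Steiner trees for tests only:
  enumerate subsets of non-terminals, keep the best MST weight over subsets
  whose union with *R* induces a connected subgraph; refuses graphs larger
  than 16 nodes. The heuristic is verified to stay within the 2× optimality
  bound on random instances (empirically it is almost always optimal at
  these sizes).
- **Determinism.** Every stochastic stage (weight draws, fold shuffles,
  synthetic generators, permutation draws) derives from an explicit
  non-negative integer seed through independent named substreams; reruns are
  bit-identical, including the pipeline's text outputs.

## Problem sizes used by the test suite

Unit tests run on toy graphs and a 300-node planted scenario. The
planted-recovery check uses the full default scenario (2000 nodes, 100 DE
genes, 20 connectors) across 10 seeds with the default ensemble settings;
the classification checks use 120-gene, 200-sample matrices with the full
100×10-fold protocol. These sizes were chosen so the complete suite documents
the method's behaviour at a realistic desk scale while remaining quick to run.

## Known limitations

- The union rule admits any gene that is internal in even one tree; on very
  dense networks this can grow the STM set slowly without bound, which is why
  the patience rule, not exhaustion, terminates the ensemble.
- The heuristic implements the printed four-step procedure exactly; no
  further local improvements (e.g., path re-optimization after pruning) are
  attempted.
- Cross-platform identifier mapping, DE-gene selection (e.g., SAM), gene-set
  enrichment services, and expression harmonization between cohorts are out
  of scope; DE lists and known-marker lists are accepted as plain text inputs.
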