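# Methods

## Model

Every quantity in the package reduces to Bernoulli block counts: a block of
`t` vertex pairs containing `e` edges and `h = t − e` holes contributes
`e ln(e/t) + h ln(h/t)` to the maximum-likelihood (ML) score (the rate set
to its MLE `e/t`, with `0 ln 0 = 0`) and `ln B(e+1, h+1)` to the fully
Bayesian score (the rate integrated out under a uniform prior).  All
computation is in log space via log-gamma; pair counts in genome-scale
networks reach ~10^7, so factorials or raw products are never formed.

A hierarchical model is a forest over the vertices.  Blocks are: one per
pair of roots (edges crossing two top-level groups), one per branching node
(edges crossing its left and right subtrees), and one per collapsed
terminal (edges within a homogeneous group).  These blocks partition the
vertex pairs; model scores are therefore sums over blocks, and sums over
independent edge-type layers for multi-layer input.  A model with `K` roots
and `R` nodes has `K(K−1)/2 + R` parameters (exposed as
`Dendrogram.num_parameters`).

## Merge ratio and greedy engine

Merging top-level clusters 1 and 2 changes only the blocks that pair them
with every other cluster `k`; the (1,2) block itself appears before the
merge as a top-level term and after it as the new node's crossing term and
cancels.  The ML merge ratio is

    log λ^ML = Σ_k [ logML(e_1k+e_2k, t_1k+t_2k) − logML(e_1k, t_1k) − logML(e_2k, t_2k) ] ≤ 0,

so for two singletons it reduces to `m ln(1/4)` with `m` the number of
outside vertices adjacent to exactly one of the two — merging is driven by
shared connectivity patterns, which is what lets the method resolve
disassortative groups that density-based scores miss.  The Bayesian
analogue `λ^B` replaces the ML kernel with the Beta marginal; its all-hole
terms do not vanish, so it sums over all other clusters.

Candidates are restricted to cluster pairs joined by an edge or sharing at
least one neighboring cluster; the engine keeps them in a max-priority
queue.  Merge scores are **not monotone** over the run (a pair can become a
better merge as the rest of the network coarsens), so pop-time staleness
checks alone are insufficient: after every merge, all candidates touching a
cluster whose counts changed are rescored and re-pushed, and version-stamp
mismatches discard the leftovers.  Ties break on the lexicographically
smallest pair of cluster minimum-member ids, making runs deterministic and
equivariant under vertex relabeling.

## Bayesian model selection

**Collapse (bottom level).**  When both children of an accepted merge are
already collapsed (singletons count as collapsed), the flat one-group model
is compared with the three-block structure:

    log λ^C = ln B(e_w+1, h_w+1) − ln B(e_11+1, h_11+1) − ln B(e_22+1, h_22+1) − ln B(e_12+1, h_12+1),

with `e_w = e_11 + e_22 + e_12`.  The node is collapsed when `λ^C ≥ 1`.
Two singletons always collapse (`λ^C = 1` identically).  No
split-multiplicity factor is applied here.  A node that fails collapse
never becomes collapsible again.  Collapsed terminals include both cliques
(density 1) and shared-neighbor groups (density 0).

**Stopping evidence (top level).**  The ratio `λ^B` alone cannot decide the
top level: the (1,2) block cancels out of it, so the density contrast
between two clusters themselves is invisible, the final `K=2 → 1` merge is
always evidence-neutral, and statistically exchangeable groups (equal
cross rates) are always pooled.  The stopping evidence therefore compares
"1 and 2 are one flat cluster" against "1 and 2 are separate clusters":

    log evidence = log λ^B + [ ln B(e_w+1, h_w+1) − ln B(e_11+1,h_11+1) − ln B(e_22+1,h_22+1) − ln B(e_12+1,h_12+1) ],

i.e. the pooling terms times the same flat merged-versus-separate term used
for collapse.  During the run (methods `ml` and `bayes`), merges with
strictly negative evidence are **deferred**; when no justified candidate
remains the gate closes — this is the point where the best merge's evidence
first drops below one — and the deferred merges are then applied, without
further collapsing, so the guide tree is always completed and link
prediction can use densities at every tree level.  Heuristic methods
(`e`, `es`, `q`) never reorder on Bayesian scores; for them the evidence is
recorded only.

**Top-level extraction.**  The reported top-level partition is obtained by
top-down descent of the finished forest: starting from the roots, a cluster
is split into its two children while the same merge evidence, conditioned
on the *current coarse partition*, does not favor keeping it whole.
Conditioning on the coarse complement matters: evaluated against the fine
clusters that existed when a merge was accepted, sampling noise in the
fine blocks systematically disfavors consolidation (each side of a
two-sided network looks heterogeneous relative to fragments of the other
side), and the cut over-resolves.  Two refinements make the descent robust:

* *Selection correction.*  The guide tree places each split point exactly
  where agglomeration found the strongest contrast, so a naive post-hoc
  Bayes factor double-dips on selection.  The split model carries a uniform
  prior over the `2^(n−1) − 1` bipartitions of an `n`-vertex cluster; the
  evidence for keeping the cluster whole gains `ln(2^(n−1) − 1)`.  The
  merge-time ratios `λ^B` and `λ^C` carry no multiplicity factors.
* *One-barrier lookahead.*  A root that merely attaches one stray vertex to
  the rest of the network has mildly positive keep-evidence while strong
  structure hides below it.  Each candidate split is therefore assessed by
  forcing it, continuing greedily with positive-gain splits inside the
  forced node's subtree, and accepting the prefix of that trajectory with
  maximal cumulative gain if positive.

Collapsed terminals have no children and are never split, so the
bottom-level clusters always refine the top level (collapsing also ceases
once the gate has closed, for the same reason).  The descent costs
`O(K_top² · (V + E))` per accepted split on top of the `O(E J log V)`-style
agglomeration; for the few-hundred-vertex networks used in the test suite
this is negligible, and for genome-scale networks it remains a small
fraction of the total run time because `K_top ≪ V`.

`stop_criterion='none'` disables the gate and reports the final roots.

## Link prediction protocol

Training networks delete a uniform random fraction of edges (at least one;
vertices are never dropped, and the degree filter is applied once before
splitting so the test universe is fixed).  The test set is the held-out
edges plus an equal number of holes sampled from the *original* network, so
a held-out edge can never appear as a negative; the training network is
asserted edge-disjoint from the held-out set on every run.  Pairs are
scored with the trained model's block densities for the layer being
predicted; ranking uses descending score with canonical pair order on ties,
the F-score is the maximum harmonic mean of precision and recall over all
cutoffs, and the AUC uses midranks so ties do not bias it.

Scoring in `cross_validate` defaults to Laplace-smoothed densities
`(e+1)/(t+2)`.  Raw ML densities `e/t` (the `LinkScorer` default, matching
the block-density definition) place every empty block at exactly zero;
collapsed shared-neighbor terminals and small sparse blocks whose few edges
were held out then rank *below* low-density cross-cluster holes, which
badly distorts AUC (measured on the planted benchmark: mean AUC 0.57 raw
versus 0.91 smoothed at a 10% hold-out).  Smoothing is a monotone
tie-breaking transform within equal-`e` blocks and leaves genuinely dense
blocks nearly unchanged.

For multi-layer input, edges are held out of the target layer only, the
model is trained jointly on all layers (candidate pairs are unioned, scores
summed), and evaluation uses the target layer's trained densities.

## Synthetic data

The generators are first-class, seeded, and emit ground-truth labels:

* `sample_planted` — planted partition: within-block rate `p_in`,
  between-block `p_out`, every pair independent.  The benchmark conditions
  used throughout the tests are 4 blocks × 8 vertices with
  `p_in = 0.8, p_out = 0.05` (assortative) and 2 blocks × 12 with the rates
  swapped (disassortative); both sit in the comfortably detectable regime
  for a Bayesian block model at these sizes while leaving realistic
  sampling noise (occasional stray low-degree vertices, occasional
  genuinely heterogeneous sub-blocks).
* `sample_hrg` — a hierarchical random graph: each pair is an edge with the
  rate of its governing node (lowest common ancestor, or terminal).
* `sample_multilayer` — independent planted layers conditioned on one
  shared block assignment (e.g. an assortative physical layer plus a
  disassortative genetic layer).

What these generators do **not** emulate about real interactomes: degree
heterogeneity (hubs), assay-specific false positives, overlapping
complexes, and correlated missingness.  Passing the planted-recovery and
link-prediction tests therefore demonstrates correctness of the model,
selection, and protocol machinery under the stated generative assumptions,
not performance claims on any particular real data set.

## Numerical and interface choices

* Counts are maintained incrementally during clustering; `recount_audit`
  and the audit mode of `tree_model_scores` recompute everything from the
  adjacency and raise on any drift (used routinely in the tests).
* `t = 0` blocks contribute exactly zero to both scores.
* Vertex ids are opaque strings; edge lists accept `#` comments, tab or
  space separators, an optional 1-based layer column, and silently drop
  duplicate pairs and self loops (with a logged count).  The "isolated or
  degree-1" filter removes vertices of degree ≤ 1 iteratively to a fixed
  point.
* Dendrograms serialize to a documented JSON format that round-trips
  losslessly; cluster assignments are TSVs sorted by vertex id with
  deterministic ids (clusters ordered by smallest member).
* The CLI (`hacnet cluster | predict | simulate`) is a thin layer over the
  library: results go to named files, logs to stderr, and a YAML config can
  pre-set any flag with explicit flags winning.

## Known limitations

* The greedy guide tree is a local optimization; on exchangeable planted
  blocks the late merge order can race stray low-degree vertices against
  cross-block pooling, which is why the stopping gate (not just the final
  cut) matters for recovery.
* The descent's lookahead crosses a single evidence barrier; two
  consecutive unfavorable splits hiding favorable structure would not be
  explored.
* Bottom-level collapse is monotone (failed collapses are final), matching
  the one-pass agglomerative design rather than any global optimum.
* Degree-corrected, weighted, and directed variants are out of scope.
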