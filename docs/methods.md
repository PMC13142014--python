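# Methods

This note records the model, the numerical and design choices, what the
synthetic data do and do not emulate, and the known limitations.

## Model and procedure

The predictor is a bagged ensemble of CART trees whose split-candidate
sampling is non-uniform. Let X be an n × p table of relative abundances and
y a binary label or a numeric response. The pipeline is:

1. **Distances.** The cophenetic (patristic) distance between features a
   and b is the sum of branch lengths on the unique path joining the two
   leaves, computed in O(p²) by one post-order sweep (pairs whose most
   recent common ancestor is node v are exactly the pairs drawn from two
   different child subtrees of v). The distance is root-invariant, so
   unrooted (basally multifurcating) inputs are accepted unchanged, and
   polytomies need no special handling. Edges without branch lengths are
   rejected rather than defaulted: silently imputing 0 or 1 would distort
   the metric.
2. **Clusters.** PAM (Kaufman–Rousseeuw BUILD + SWAP, best-improvement
   swaps, no restarts) on the distance matrix, with k chosen by maximizing
   the average silhouette width over k = 2..min(10, p − 1); ties go to the
   smaller k. Silhouette uses Rousseeuw's conventions (singleton clusters
   contribute 0; 0/0 is 0). All PAM ties — BUILD gains, SWAP deltas,
   nearest-medoid assignment — break by lexicographic feature label with a
   1e-9 relative tolerance. Index-based tie-breaking was rejected because
   exact BUILD gain ties are *generic* (two candidates covering an isolated
   pair of points produce identical gains), which would make the partition
   depend on column order; label-based ties keep it permutation-stable.
   BUILD+SWAP is a local optimizer: on random Euclidean instances with
   p ≤ 8, k = 2 it reaches the enumerated global optimum on ~90% of
   instances and is otherwise swap-stable (no single exchange improves it);
   R's reference implementation returns the same solutions on the instances
   we inspected.
3. **Localized importance.** For each cluster, forests are grown on the
   cluster's features only (uniform within-cluster weights) for each mtry
   candidate {⌈q_k/10⌉, ⌈√q_k⌉, ⌈log₂ q_k⌉} (clamped to [1, q_k],
   deduplicated), and out-of-bag permutation importances are averaged
   across candidates. One permutation per tree's OOB set is the default
   (`n_permutations` raises it). A single-feature cluster gets a
   one-feature forest; its importance may be ≈ 0 or negative and is handled
   by the clipping step. The second candidate is read as ⌈√q_k⌉; the
   literal "all features" reading is available as `mtry_grid="literal"`.
4. **Probability integration.** Negative scores are clipped to zero
   (feature elimination), scores are normalized within clusters
   (v, unit-sum per cluster), and each v_j is multiplied by its cluster's
   size share q_k/p, so every cluster carries total mass q_k/p and Σw = 1.
   A *degenerate* cluster (all clipped scores zero) would produce 0/0; its
   features get w = 0 and the final w vector is renormalized, which
   preserves the relative masses of the surviving clusters. If every
   cluster is degenerate the model falls back to uniform w with a warning
   rather than failing. Note the structural consequence: a non-degenerate
   cluster's mass is pinned at q_k/p regardless of how strong its features
   are, so the total mass on any feature subset is capped by the size share
   of the clusters containing it. Concentration beyond that share can only
   come from clipped co-members or degenerate-cluster renormalization —
   the method equalizes opportunity across clusters by design.
5. **Final forest.** mtry is tuned by OOB error over the analogous
   candidates on p′ (the count of non-zero w), all candidates evaluated
   with the same seed (paired bootstraps), ties to the smaller value; the
   final forest draws each node's candidates without replacement with
   probability ∝ w (Efraimidis–Spirakis sampling via exponential keys), so w_j = 0
   features can never split.

Boundary modes: `cluster_mode="disjoint"` (k = p) short-circuits to exactly
uniform w — running the importance arithmetic on p singleton clusters could
eliminate features whose noise importance is ≤ 0, whereas this boundary is
defined as the standard uniform forest; `cluster_mode="single"` (k = 1)
runs the full arithmetic on one cluster and reduces to clipped-normalized
global importance.

## Forest engine

Trees are grown to purity with no depth limit; a node is a leaf when its
size is below the minimum (1 for classification, 5 for regression), it is
pure, or no candidate has two distinct values. Split criteria are Gini
impurity and variance reduction; thresholds are midpoints of adjacent
distinct values (when the two values are adjacent doubles and the midpoint
rounds onto the upper one, the lower value is used so neither child can be
empty); criterion ties break to the lower feature index, then the
lower threshold (realized by scanning candidates in ascending feature order
and keeping the first strict maximum). Classification leaves store class-1
proportions so AUC can use averaged proportions; majority-vote ties go to
the lexicographically smaller label. OOB error aggregates hard votes
(classification) or means (regression) over the trees for which a sample is
out-of-bag; never-OOB samples are excluded with a warning. The inner loops
(growth, traversal, permutation importance) are numba kernels; model state
is plain flat arrays, serialized to JSON and exactly round-trippable.

One global seed expands through `numpy.random.SeedSequence` spawning into
per-stage and per-tree generators, so any stage is independently
reproducible and two fits with the same seed are bit-identical.

## Synthetic data

`simulate_dataset` emulates the target regime: a pure-birth (Yule) tree
with i.i.d. exponential branch lengths (mean 0.1); zero-inflated,
log-normally skewed counts built by masking a per-feature baseline
(log-mean ~ N(0,1), log-noise σ = 1) with structural zeros (π₀ = 0.5 by
default), scaling to a uniform library size in [5,000, 50,000] and
rounding; and an outcome driven by the standardized summed relative
abundance of one clade, chosen as the clade closest in size to a target
share (25% by default; an error is raised if no clade is within 50% of the
target). Classification draws Bernoulli outcomes on the logistic scale and
regression adds unit Gaussian noise, both with effect size β = 5 on the
standardized clade abundance. A `scattered` mode places the same number of
signal features at random positions for no-phylogenetic-advantage
controls.

What this does *not* emulate: compositional correlation structure between
taxa (features are independent given their baselines), overdispersion
beyond the log-normal, batch effects, sequencing depth confounding, and
real tree shapes (Yule trees are more balanced than many 16S trees).
Passing tests therefore demonstrate correctness of the algorithmic
machinery and the direction of the methodological effect under a favorable
generative model, not effect sizes on real data.

## Cross-validation harness

Five folds, stratified for classification (the small-n folds otherwise risk
losing a class; regression uses plain shuffled folds), all seeded. The
clustering is computed from the tree alone and shared across folds; the
importance, probability, tuning and training stages see training rows only,
and the test fold is first touched at prediction time (the suite verifies
this by corrupting held-out rows before a refit). Metrics: error rate and
AUC — computed from averaged class proportions by the Mann–Whitney rank
statistic with midranks — or RMSE and MAE. `compare_variants` runs the
three variants under identical folds and seeds and also reports the
variance of each fold's probability vector (computed after subtracting the
first entry so the uniform vector gives exactly zero).

## Problem sizes in tests and the acceptance script

The production defaults (10,000 trees, 1,000 cluster trees) are
configurable; the test suite and acceptance script use reduced ensembles
chosen to keep Monte-Carlo noise acceptable at desk scale: the paired
variant comparison runs 20 replicates of n = 80, p = 100 (p > n, the
regime the method targets, where elimination and weighting have room to
help) with 300/150 trees; parameter-recovery fits use the n = 120, p = 40,
25%-clade design with 500/500 trees; regression mirrors the classification
design with 10 replicates. All replicate seeds derive from the single
`--seed` argument.

## Known limitations

* Binary classification only; multiclass outcomes are rejected.
* No missing values, sample weights, or categorical features.
* PAM is O(k·p²) per SWAP pass and the distance matrix is dense O(p²);
  for p in the tens of thousands a CLARA-style subsampler would be needed.
* The silhouette search range (2–10) follows standard practice and is
  exposed as `k_min`/`k_max`; nothing guarantees the optimum lies inside.
* Importance-based elimination is aggressive when cluster forests are
  small: with few trees, weak signal features can be clipped to zero.
  Raising `n_trees_cluster` or `n_permutations` stabilizes the scores.
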