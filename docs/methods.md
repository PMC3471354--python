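# Methods

## Model and score

A pathway is an undirected graph *P = (G, I)* of genes and physical or
functional interactions; it may be disconnected and may contain isolated
genes. Given case and control expression samples, each gene receives a
two-sided Welch (unequal-variance) *t*-test p-value *p(g)* with
Welch–Satterthwaite degrees of freedom, mapped to *z(g) = Φ⁻¹(1 − p(g))*.
Any procedure producing per-gene p-values could be substituted; Welch is the
default because only the means are hypothesised equal, not the variances.
No per-gene cut-off is applied — weak individual signals may still be
significant in aggregate.

A subgraph *Q* with edge set *I′* is scored by the degree-weighted
Liptak–Stouffer statistic z(Q) = Σ d_Q(g)·z(g) / √(Σ d_Q(g)²), where
d_Q(g) counts the edges of *I′* at *g*. Dividing by the root of the squared
degree sum makes z(Q) exactly standard normal for any *fixed* Q under iid
N(0,1) gene scores, so subgraphs of different size and shape are comparable.
Because degree-0 genes contribute nothing to either sum, a subgraph is
represented canonically by its edge subset, making the search space 2^|I|;
z(∅) is defined as 0, the null expectation (the formula itself is 0/0).

### p-value clamping

p-values are clamped to [1e-15, 1 − 1e-15] before the quantile transform;
Φ⁻¹(0) and Φ⁻¹(1) are infinite and a single infinite z(g) would poison every
score containing that gene. The bound corresponds to |z| ≈ 7.94, far beyond
any z attainable at realistic sample sizes, so the clamp is inert except for
exactly degenerate inputs (both groups constant: p = 1 for equal means, the
clamp floor for unequal means). Genes with fewer than two samples in either
class cannot form a t statistic and are excluded with a log message.

## Search

Maximising z(Q) over edge subsets is closely related to maximum-weight
subnetwork problems known to be NP-complete, so the search is simulated
annealing:

* **Initialisation** — each interaction included independently with
  probability 0.5 (configurable; 0 gives an empty start).
* **Proposal** — a node or edge of the *parent* pathway is drawn uniformly
  from the combined pool of |G| + |I| elements (one pool, not a coin flip
  between two pools). An edge toggles in/out. A node with at least one
  current incident edge is "present": toggling it removes all its current
  edges; an absent node's toggle inserts all of its parent edges. Node moves
  matter: edge-only proposals explore much more slowly and are kept only as
  an option (`edge_moves_only`).
* **Acceptance** — improving moves always; worsening moves with probability
  exp((z′ − z)/T). A rejected proposal leaves the current state unchanged.
* **Cooling** — T decreases geometrically from t_start = 100 to
  t_end = 10⁻⁵ over 100·|I| iterations (both configurable); the
  per-iteration factor is exp(log(t_end/t_start)/n_iter), so the schedule
  lands on t_end exactly (to fp rounding).
* **Reporting** — the best subgraph ever visited is returned. Returning the
  final state instead (the textbook loop) is strictly dominated and is kept
  behind `AnnealParams.final_state` for comparison experiments.

The inner loop (subpert/_core.py) maintains the score's numerator and
squared-degree sum incrementally (O(1) per edge toggle), keeping the degree
accumulator in exact integer arithmetic; the winner's score is recomputed
exactly from its edge set afterwards, so accumulated float drift in the
numerator can only influence the trajectory, never the reported score. All
randomness is pre-drawn from three child PRNG streams (initialisation,
proposals, acceptance), which (a) makes the numba-JIT path and the
pure-Python fallback bit-identical and (b) makes runs with a larger
iteration budget exact extensions of shorter runs, so the reported
best-ever score is monotone in `iteration_multiplier` for a fixed seed.

`brute_force_max_subgraph` enumerates all 2^|I| subsets by a Gray-code walk
(one O(1) toggle per subset) and is the validation oracle; it refuses
pathways above a configurable cap (default 20 interactions). Ties within
1e-12 are broken toward fewer edges, then the lexicographically smallest
edge list, so the oracle is deterministic.

## Significance

z(P̂) cannot be referred to N(0,1): the search maximises over subgraphs and
gene scores may be correlated. The null is instead built by relabeling: the
pathway's genes are replaced by a uniform without-replacement draw from a
*universe* of genes, preserving the interaction structure exactly
(isomorphic relabeling; sampling without replacement keeps the null pathway
a simple graph), and the identical annealing search is run on each of k
relabeled pathways. The universe defaults to all measured genes and can be
restricted by a user-supplied gene list (e.g. to genes present in an
interactome); the observed pathway's own genes are not excluded. The
empirical p-value is the strict-exceedance fraction #{z(P̃) > z(P̂)}/k; a
pseudocount mode (count+1)/(k+1) avoids literal zeros when ranking matters.
Benjamini–Hochberg step-up adjustment is applied jointly across all pathway
× condition pairs of a screen (per-condition families optional). Pairs with
no measured interaction are skipped before the BH family is formed.

Per-pair seeds derive from the master seed and a CRC32 of
"pathway|condition", and per-trial null seeds from (seed, trial-index) seed
sequences: every pair and trial is reproducible in isolation, and adding a
pathway to a screen does not change any other pair's numbers.

## Synthetic data

The generator emulates a curated-pathway × case-control microarray study:
a uniform random simple graph (n_genes = 60, n_edges = 100 by default), a
planted sub-pathway grown edge-by-edge by randomized breadth-first growth
(25% of interactions by default, connected where the graph allows), and iid
Gaussian expression — control samples N(0, σ), case samples shifted by
2.5 σ at every gene incident to a planted edge (15 + 15 samples by
default). Optional background genes extend the measured universe without
joining the pathway. The generator deliberately omits gene–gene expression
correlation, platform/batch effects, and heavy-tailed noise: passing tests
show correct behaviour of the statistic, search and calibration under the
model's own assumptions, not robustness to real microarray artefacts. The
perturbation is applied to genes (endpoints of planted edges), not edges,
since expression is a node-level signal.

### A note on planted-set recovery

Recovery of the planted edge set is evaluated by edge-level Jaccard between
the annealer's best subgraph and the planted subgraph. Under the default
conditions this averages ≈ 0.44, and the gap is a property of the statistic,
not of the search: the returned subgraph is single-edge locally optimal and
scores strictly above the planted set itself. With ~25 planted edges the
marginal cost of attaching one more edge at a degree-1 perturbed gene is
≈ (Σd·z/Σd²)·(d+1) ≈ the mean planted z, so any background neighbour with
z(g) ≳ 0 *belongs* in the optimum, while planted leaf edges with
below-average z at high-degree hubs are pruned. By homogeneity of z(Q) the
effect is scale-invariant — raising the planted shift to 5 σ or 10 σ moves
mean Jaccard only to ≈ 0.45/0.48 — so the maximiser of this score is a
systematically "fuzzier" object than the planted subgraph. Users should
read the best sub-pathway as the evidence-optimal subgraph, not as a sharp
boundary of the perturbed region.

## Calibration checks and problem sizes

The acceptance suite verifies, end to end: the analytic adjusted-p floor of
a permutation screen (with k permutation trials and m pairs, a unique
minimal raw p of 1/k adjusts to m/k); Monte-Carlo standard-normality of
z(Q) for a fixed 6-gene/7-interaction subgraph (10⁵ replicates, 4-SE
tolerance); exact landing of the cooling schedule (rel. 1e-9); agreement of
the annealer with the exhaustive oracle on 200 random instances with
|I| ≤ 12 (≥ 95% required; measured 99%, never above the optimum); and
uniformity of global-null empirical p-values (200 trials × 200
permutations on the 6-gene pathway with a 40-gene universe; KS test at
α = 0.01 plus an exact-binomial check of the p ≤ 0.05 rate). These sizes
keep each check cheap while leaving Monte-Carlo error well below the
tolerances tested.

## Known limitations

* Interactions are undirected, and the direction of differential expression
  is ignored: the two-sided p-value is direction-blind, so strongly up- and
  strongly down-regulated genes both receive large positive z(g) and a
  "perturbed" sub-pathway may mix the two. Signed/directional scoring is
  out of scope.
* The best sub-pathway is not required to be connected, by design.
* Gene identifiers are matched by exact trimmed string equality; no alias
  resolution.
* The annealer is a heuristic: on some instances it returns a near-optimal
  local maximum (see the worked example); the permutation test inherits the
  same search on null pathways, which keeps observed and null scores
  comparable.
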