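# Methods

`metasyn` implements a network-based workflow for explaining why some drug
combinations are synergistic in a cancer cell line: drug-pair target signal
is diffused over a cell-line-specific gene-interaction network, the diffused
profiles are compressed into *metagenes* by graph-regularized non-negative
matrix factorization, and downstream statistics connect metagene loadings to
measured synergy scores. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Cancer network construction

The analysis network is an undirected, unweighted gene graph. It is built
from a generic interaction edge list in two filtering passes:

1. **Cancer-gene restriction.** The union of one or more cancer-related gene
   sets is formed (case-normalized exact symbol matching; alias resolution
   is deliberately out of scope and treated as input preparation), and only
   edges with both endpoints in the union are kept.
2. **Loss-of-function removal.** Genes carrying loss-of-function mutations
   in the modelled cell line are deleted together with their edges, on the
   assumption that an inactive gene cannot transmit signal. Gain-of-function
   and unknown-category mutations are retained.

After *each* pass, genes left without any neighbour are pruned. Pruning
after the LoF pass is a package choice: degree normalization downstream
requires every node to have degree ≥ 1, so isolated nodes cannot be carried
anyway. Self-loops and duplicate edges in inputs are dropped with a logged
count. Gene order is lexicographic everywhere, so the adjacency matrix `A`,
degree matrix `D` and all derived matrices are bit-reproducible.

## Combination dataset

A combination dataset couples unordered drug pairs carrying four synergy
scores — HSA (excess over the highest single agent), ZIP (excess over a
zero-interaction potency model), Bliss (excess over independence) and Loewe
(excess over dose additivity); positive values mean synergy — with per-drug
target sets. Pairs are canonicalized (`drug_a < drug_b`) and replicate rows
of the same unordered pair are collapsed by averaging each score.

Filtering keeps, per drug, only targets whose action label is inhibitory
(default vocabulary: inhibitor, antagonist, blocker, negative modulator,
suppressor — configurable, since source vocabularies are free text) *and*
whose gene is a node of the analysis network. Drugs left with no usable
target are dropped along with every combination containing them. A drug's
post-filter target count is the `n` used in seed weighting; targets outside
the network deliberately do not count, because they receive no seed mass.

Quartiles of a synergy metric use the linear-interpolation convention;
quarter membership uses half-open intervals with boundary ties assigned to
the lower quarter.

## Random walk with restart

For a pair (drug 1 with n₁ in-network targets, drug 2 with n₂), the seed
vector x₀ places 0.5/n₁ on each of drug 1's targets and 0.5/n₂ on each of
drug 2's, summing contributions on shared targets, so x₀ always sums to 1.
The propagated profile is the closed form

    x_T = α [I − (1 − α) A D⁻¹]⁻¹ x₀

with restart probability α (default 0.5, balancing local and network-wide
diffusion). Because A D⁻¹ is column-stochastic, x_T is a probability
vector: non-negative and summing to 1 (mass conservation). Since the graph
is undirected, the degree in `D` is plain degree. The resolvent is
LU-factorized once per network and reused for every combination; at a few
thousand genes the dense solve is cheap. A power-iteration solver is kept
as an independent cross-check of the closed form.

Profiles are stacked into the genes × combinations matrix `X` and
transformed elementwise to `X′ = −log X` before factorization: propagated
scores are heavily right-skewed (direct targets dominate), and the log
compresses that tail. The natural logarithm is used; any other base only
rescales `X′` and is absorbed by the factorization's scale freedom. Entries
below a floor (default 1e−12; exact zeros occur only when a connected
component contains no seed mass) are clamped to the floor, which also keeps
`X′` finite and non-negative. Note the transform reverses order: the genes
*most* affected by a pair have the *smallest* transformed values, which is
why metagene membership is read from the smallest weights of `W`.

## Graph-regularized NMF

`X′` (N × M) is factorized as `X′ ≈ W H` with `W` (N × K) and `H` (K × M)
non-negative. Each column of `W` is a metagene; `H` gives each
combination's loading on each metagene. The graph Laplacian `L = D − A`
penalizes rough metagenes so that interacting genes receive similar
weights:

    J(W, H) = ‖X′ − W H‖²_F + λ · tr(Wᵀ L W),     0 ≤ λ ≤ 1

minimized by the standard multiplicative updates

    W ← W ⊙ (X′ Hᵀ + λ A W) ⊘ (W H Hᵀ + λ D W)
    H ← H ⊙ (Wᵀ X′) ⊘ (Wᵀ W H)

which preserve non-negativity and weakly decrease J at every step
(denominators stabilized with ε = 1e−10). A convex-mixture variant,
`(1 − λ)‖·‖² + λ tr(·)`, is available behind `convex_mix=True`; it is the
natural reading of a λ bounded by 1, and at small problem sizes it is the
form under which λ = 0.9 exerts visible smoothing pressure (in the pure
penalty form the reconstruction term dwarfs the penalty). Default λ = 0.9,
favouring adherence of metagenes to network structure.

Initialization is i.i.d. uniform(0, 1) scaled by mean(X′)/K; `n_restarts`
(default 5) independent initializations are run with seeds derived
deterministically from `(rng_seed, K)` — so a K scan and a direct fit at
the same K see identical restarts — and the lowest-objective solution is
returned. Stopping: relative objective change < `rel_tol` (default 1e−6) or
`max_iter` (default 1000).

**Scale indeterminacy.** `W diag(c)` and `diag(c)⁻¹ H` represent the same
model. Before clustering or comparing H rows, factors are normalized to
unit-L2 metagene columns with H compensated (`normalize_factors`), leaving
`W H` unchanged. Without this step, comparisons across H rows would be
meaningless.

**Model order.** K is chosen at the elbow of the reconstruction-error curve
(pure reconstruction term ‖X′ − WH‖_F, excluding the penalty, so the curve
measures fit alone) over a K scan. The elbow is the Kneedle criterion for a
decreasing convex curve: min–max normalize (K, error) and return the K
maximizing the vertical distance between the curve and the chord joining
its endpoints. A near-linear curve has no elbow and raises an error
advising a wider range.

## Downstream statistics

All rank tests use exact null distributions for n ≤ 25 without ties and the
normal approximation with continuity correction otherwise; zero differences
are dropped in signed-rank tests; "FDR" is Benjamini–Hochberg everywhere.

* **Quartile gene screen.** Per gene, a two-sided Wilcoxon rank-sum test
  compares propagated scores of bottom-quartile vs top-quartile synergy
  combinations; BH adjustment across all genes; significance below
  `screen_alpha` (default 1e−4). Rank-based, hence invariant to the −log
  transform. Constant genes get p = 1.
* **Gene–synergy correlation.** Spearman ρ over all combinations, p by the
  t approximation, BH-adjusted across exactly the genes requested; constant
  genes are reported missing.
* **Clustering.** Ward-D2 agglomeration of H columns under Euclidean
  distance (scipy linkage `ward`, whose heights match the D2 convention:
  two singletons merge at their Euclidean distance).
* **Enriched-cluster selection.** The dendrogram is cut at every height
  creating a new partition; every cluster with ≥ `min_cluster_size`
  (default 10) members whose mean synergy exceeds the global third quartile
  (computed once over all retained combinations, per metric) for at least
  one metric is a candidate; identical member sets from different cuts are
  collapsed keeping the lowest qualifying height. Candidates related by
  nesting form lineages (connected components of the subset-comparability
  graph); per lineage, the candidate with the highest best qualifying
  per-metric mean is kept (an all-metric-mean alternative is a documented
  config choice), so final clusters are pairwise non-nested. Most-frequent
  drug ties break lexicographically.
* **Metagene dominance.** Pooling the deduplicated members of all final
  clusters, each metagene is compared with every other by a one-sided
  paired Wilcoxon signed-rank test on H loadings, BH-adjusted within the
  K − 1 comparisons; dominance requires every adjusted p < `fdr_q`
  (default 0.05).
* **Per-drug split.** One drug's combinations are Ward-split into two
  groups; the group with the higher mean loading on the tested metagene is
  "high"; per metric, a one-sided Welch t-test (direction fixed a priori:
  high > low) compares synergy. Identical loading columns make the split
  arbitrary; this is flagged and warned.
* **Partner-drug test.** Per (drug, metric), a one-sided one-sample
  signed-rank test of scores > 0, BH-adjusted across all tested cells.

## Synthetic data and what it does (not) show

The generator emulates the four inputs with known ground truth:

* **Network**: a stochastic block model, 300 genes in 6 modules, within- and
  between-module edge probabilities 0.25 / 0.01; only the largest connected
  component is kept. Modules stand in for pathways; the SBM was chosen over
  degree-matched rewiring for directly controllable module structure.
* **Drugs**: 30 drugs, 1–4 inhibitory targets each. Each drug has a home
  module (sampled with the designated synergy module at twice the weight of
  the others, so planted pairs are numerous enough to populate
  cluster-sized groups); the first target is guaranteed in the home module
  and the rest fall there with probability 0.8.
* **Combinations**: 120 unique pairs, of which a fraction (default 0.2) are
  *planted*: both drugs' home module is the designated synergy module. Each
  of the four scores is baseline Normal(0, noise_sd = 3) plus, for planted
  pairs, the effect δ = 8 scaled by fixed per-metric factors
  (1.0 / 0.8 / 0.9 / 0.6 for HSA/ZIP/Bliss/Loewe) — four noisy views of one
  latent effect, mimicking the partial agreement among real synergy models
  without simulating dose–response surfaces.
* **Mutations**: 5% of genes outside the planted module are labelled
  loss-of-function (the planted module is protected so the signal survives
  network filtering), plus gain-of-function and unknown labels.

The recovery experiment (`run_synthetic_recovery`) runs the full pipeline
on one draw: LoF filtering, dataset filtering, propagation, −log, a K scan
over 2–12 with elbow selection (cheap scan settings: 2 restarts, 300
iterations), then the final GNMF fit with λ = 0.9 under the convex-mixture
objective and 12 restarts — more than the library default because
split-basis local minima, in which two metagenes share the planted module
and neither dominates, occur occasionally with fewer restarts. It then
identifies the metagene whose smallest-weight gene list best overlaps the
planted module and measures (i) whether that metagene passes the dominance
test, (ii) the planted-pair purity of the best final cluster, and (iii) the
precision of the quartile screen with respect to the planted module.

Screen precision is measured over *positively associated* flagged genes
(median propagated score higher in the top than the bottom quartile).
Because propagation conserves mass, combinations concentrated on the
planted module necessarily drain score from other modules, so genes
elsewhere become genuinely significant with negative association; counting
those as false positives would misread a real property of the diffusion.

The fixture scale (300 genes / 120 combinations, K scan to 12) keeps a full
recovery run in seconds on one CPU. What passing shows: the pipeline's
statistics recover module-level planted structure under additive Gaussian
score noise with a modular network. What it does not show: robustness to
scale-free topology, correlated assay noise, alias mismatches, weighted or
directed interactions, or activating drug mechanisms — none of which the
generator models.

## Numerical and degenerate-input choices

* Propagated profiles are clipped at 0 and renormalized to column sum 1 to
  remove solver round-off (drift is at machine precision).
* Constant gene rows: screen p = 1, correlation reported missing.
* All synergy scores equal: a single quarter, with a warning.
* Duplicate H columns: zero-height merges are legal; a fully degenerate
  per-drug split is flagged.
* All-zero score vectors in signed-rank tests: p = 1.
* Flat or strictly linear error curves: elbow detection refuses rather than
  guessing.

## Known limitations

* Only inhibitory drug action is modelled; activators would require signed
  propagation.
* The propagation treats all interactions as equally reliable, unweighted
  and undirected.
* GNMF is non-convex: cluster compositions can vary with initialization
  even when the dominant metagene is stable; restarts mitigate but do not
  eliminate this.
* Exact symbol matching means upstream identifier hygiene is the caller's
  responsibility.
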