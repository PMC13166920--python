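# metasyn

Network-propagation and metagene analysis of drug-combination synergy.

## The problem

Synergy screens report, for each drug pair tested on a cancer cell line,
summary scores under several reference models (HSA, ZIP, Bliss, Loewe;
positive = synergistic). The scores say *which* pairs are synergistic, but
not *why*: the measured quantity is phenotypic, while the mechanism lives in
the signaling network connecting the drugs' targets. `metasyn` is for
computational biologists who want a mechanistic, pathway-level explanation
of synergy from three simple ingredients: an interaction network, a
drug-target table, and the synergy scores themselves.

## The method

1. **Cell-line-specific network.** A generic gene-interaction edge list is
   restricted to a combined cancer gene set; genes with loss-of-function
   mutations in the cell line (considered unable to transmit signal) are
   removed, and isolated genes pruned.
2. **Random walk with restart (RWR).** Each pair's targets define a seed
   vector x₀ (0.5/n₁ on drug 1's n₁ targets, 0.5/n₂ on drug 2's, summed on
   shared targets). The propagated profile is the closed form

       x_T = α [I − (1 − α) A D⁻¹]⁻¹ x₀,   α = 0.5 by default,

   turning sparse target annotations into network-wide molecular profiles.
   Profiles form a genes × combinations matrix X with unit column sums.
3. **Graph-regularized NMF (GNMF).** X′ = −log X is factorized as
   X′ ≈ W·H with the graph-Laplacian penalty λ·tr(WᵀLW) (λ = 0.9) so that
   interacting genes get similar weights. Columns of W are *metagenes* —
   pathway-level gene groups; H holds each combination's metagene loadings.
   The number of metagenes K is picked at the elbow of the
   reconstruction-error curve.
4. **Synergy statistics.** Per-gene quartile screens (Wilcoxon rank-sum,
   BH-FDR) and Spearman correlations link propagated scores to synergy;
   Ward-D2 clustering of H plus an exhaustive dendrogram-cut scan finds
   clusters whose mean synergy exceeds the global third quartile; paired
   signed-rank tests identify metagenes whose loading dominates in those
   clusters — the candidate mechanistic signature of synergy.

A synthetic-data module generates all inputs with known ground truth
(modular network, module-homed drugs, synergy planted on pairs co-targeting
a designated module), so the whole pipeline is testable offline and
planted-structure recovery is measurable.

## Worked example

```python
import metasyn as ms

outcome = ms.run_synthetic_recovery(ms.SyntheticConfig(rng_seed=7))
res = outcome.result
print("selected K:", res.factorization.k)
print(res.report.to_string(index=False))
print(res.dominance.to_string(index=False))
```

prints

```
selected K: 6
 cluster_id  cut_height  n_pairs           HSA           ZIP         Bliss         Loewe most_frequent_drug  n_pairs_with_drug
          1       21.34       10 8.34 +/- 2.47 7.34 +/- 2.48 8.49 +/- 4.00 4.71 +/- 3.38               D006                  4
 metagene  max_adj_p  dominant
        0   1.000000     False
        1   1.000000     False
        2   1.000000     False
        3   1.000000     False
        4   0.000977      True
        5   1.000000     False
```

Reading it: the elbow scan chose K = 6 metagenes; one 10-pair cluster has
mean synergy above the global third quartile on all four metrics (e.g. HSA
8.34 ± 2.47 against a background of mean ≈ 0); and metagene 4 — whose
smallest-weight genes coincide exactly with the planted network module
(`outcome.planted_overlap == 1.0`) — is the single metagene whose loadings
significantly exceed every other metagene's across the cluster members
(worst BH-adjusted signed-rank p = 0.00098). On real data the analogous
output names the metagene, and hence the gene neighbourhood, that
distinguishes highly synergistic combinations; `ms.top_genes` extracts its
ranked gene list for pathway-enrichment services.

Every stage is also exposed on the command line (`metasyn simulate`,
`build-network`, `propagate`, `factorize`, `analyze`); pass `--help` for
options.

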