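# phenoprop

Network propagation for rare-disease etiology and candidate-gene
prioritization.

Rare monogenic disorders — the motivating case being primary ciliopathies,
caused by dysfunction of the cilium and spanning retinal, renal, CNS and
skeletal phenotypes — are genetically heterogeneous: each disease has only
a handful of confirmed genes, different diseases share overlapping gene
sets, and clinically similar disorders often share *no* genes at all.
`phenoprop` implements a guilt-by-association framework that works on a
protein–protein interaction (PPI) network instead of on gene lists:

- **Propagation profiles.** Each trait's seed genes define a restart
  distribution `r` (equal weight on every seed), and the trait's profile is
  the personalized-PageRank stationary solution
  `x = d·Pᵀx + (1−d)·r`, with `P` the (weighted) row-stochastic walk matrix
  and damping `d = 0.85` by default. Scores sum to one and measure every
  protein's proximity to the seeds.
- **Trait comparison.** Traits are compared by Euclidean distance between
  z-scored profiles (and, as the baseline, by Jaccard distance of seed
  sets), clustered with Ward-D2 linkage, and evaluated by how well small
  distances recover trait pairs sharing a clinical organ phenotype (AUROC
  with a stratified bootstrap CI).
- **Protein modules.** The network is partitioned by recursive Walktrap
  clustering (re-clustering modules above 20 genes, up to 5 rounds) and
  modules are associated to traits by one-sided Wilcoxon rank-sum tests of
  module scores against the whole network, BH-adjusted per trait, requiring
  at least one seed gene in the module.
- **Cross-species transfer.** Model-organism (mouse) phenotypes nearest to
  a disease in propagation space are selected; the disease's own genes are
  removed from their seed sets, propagation is re-run, and per-gene scores
  are combined by geometric mean into a ranking that recovers held-out
  disease genes.
- **Prioritization model.** Per-disease features — 1 − permutation p-value
  of the propagation score (1,000 random-seed permutations by default),
  1 − normalized cross-species aggregate rank, and an expression-model
  score — are min–max scaled and integrated by one pooled logistic
  regression trained over disjoint 5-gene training rounds (150 sampled
  negatives per round). Evaluation reports PR AUC, McClish-standardized
  partial AUROC (specificity 0.95–1.0) and AUROC.
- **Enrichment.** Final rankings (seeds excluded) are tested by preranked
  GSEA (weighted Kolmogorov–Smirnov running sum, gene-label permutation
  null, BH across sets, max set size 2,000).

Because the real inputs are large external database releases, the package
ships a first-class synthetic-world generator (`phenoprop.synthetic`): a
planted-partition graph with dense functional modules, human and mouse
traits seeded from those modules with noise, organ labels aligned to
modules, and an expression matrix with planted cell-type signal — so every
stage can be validated against known truth.

## Worked example

```python
import phenoprop as pp

cfg = pp.SyntheticWorldConfig(n_human_traits=12, rng_seed=1)
world = pp.generate_world(cfg)

prop = pp.NetworkPropagator(damping=0.85).fit(world.network)
profiles = prop.profiles(world.human_traits)

rec_prop = pp.evaluate_phenotype_recovery(
    pp.propagation_distance_matrix(profiles), world.organ_annotations, rng_seed=0)
rec_jac = pp.evaluate_phenotype_recovery(
    pp.jaccard_distance_matrix(world.human_traits), world.organ_annotations, rng_seed=0)

partition = pp.recursive_walktrap(world.network, max_size=20, max_rounds=5)
assoc = pp.associate_modules(partition, profiles, world.human_traits)

bench = pp.benchmark_gene_recovery(world.human_traits, world.mouse_traits,
                                   world.network, k=10, rng_seed=0)
```

which prints (formatted):

```
world: 300 genes, 1413 edges, 12 diseases, 20 mouse phenotypes
phenotype-pair recovery AUROC: propagation 0.680 (95% CI 0.497-0.835), Jaccard 0.651
modules: 49 detected, 25 significant module-trait associations
held-out gene recovery AUROC: nearest phenotypes 0.717, random phenotypes 0.592 (paired p = 5.83e-07)
```

Read: on a 300-gene planted world, propagation distances recover
phenotype-sharing disease pairs better than seed-gene overlap does;
Walktrap finds the planted modules and the rank-sum test links them to the
right diseases; and selecting the ten nearest mouse phenotypes recovers
held-out disease genes far better than random phenotypes (the
cross-species signal the prioritization model then exploits).

A thin CLI mirrors the library: `phenoprop simulate | propagate | permute |
compare | modules | mouse | expression | prioritize | gsea` (see
`phenoprop --help`).

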