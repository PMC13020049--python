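# Methods

## Propagation model

A trait's propagation profile is the personalized-PageRank solution
`x = d·Pᵀx + (1−d)·r` on the undirected weighted interaction network, with
the restart vector `r` uniform over the trait's seed genes (every seed gets
equal weight before normalization). `P` is row-stochastic; by default edge
confidences are used as transition weights (a flag disables this). Because
the adjacency is symmetric, `Pᵀ = W·D⁻¹`, so the solver is a sparse
mat-vec power iteration; it stops when the L1 residual drops below `tol`
(default 1e-12, cap 1000 iterations — at d = 0.85 the residual contracts by
d per step, so ~170 iterations suffice) and raises on non-convergence.
Nodes exist only as edge endpoints, so there are no dangling nodes and
every profile sums to one. The damping parameter is the probability of
following an edge rather than restarting; 0.85 is the convention of the
igraph implementation this mirrors, and it is exposed in
`PropagationConfig`. Batched propagation (many restart vectors at once)
backs the permutation machinery.

**Permutation nulls.** To keep well-connected hub genes from dominating,
raw scores are converted to empirical p-values against propagations from
random seed sets of the same size, drawn uniformly over network nodes
without degree matching (degree-matched sampling can be added for
sensitivity analysis but is not the default). The add-one convention
`p = (1 + #{permuted ≥ observed}) / (B + 1)` keeps p ≥ 1/(B+1), valid
under BH. Default B = 1000; calibration checks use B = 499 for speed.

**Standardization.** Per-trait z-scoring across nodes uses the population
SD; expression rows are scaled with the sample SD (n−1). The two
conventions are stated because they differ and both were genuinely open.

## Trait comparison

Jaccard distance (1 − |A∩B|/|A∪B| of seed sets) is the gene-overlap
baseline; the propagation distance is the Euclidean distance between
z-scored profiles. Hierarchical clustering uses scipy's Ward linkage on
the precomputed distance matrix, i.e. the Lance–Williams recurrence on
squared distances (the Ward-D2 convention — implementations differ, so
this is pinned). Phenotype-pair recovery treats unordered trait pairs
sharing ≥ 1 organ label as positives and −distance as the classifier
score; AUROC comes from the midrank Mann–Whitney identity and the 95% CI
from a stratified bootstrap (positives and negatives resampled
independently, percentile interval, 2000 replicates by default).
Per-phenotype AUROCs keep pairs sharing *other* phenotypes among the
negatives (a flagged alternative excludes them).

## Module detection and association

Walktrap community detection (walk length 4, the cited implementation's
default) is run per connected component; any module above `max_size = 20`
genes is re-clustered as an induced subgraph, recursing to `max_rounds =
5`. Modules that refuse to split (single-cluster result) or are still
oversized at the cap are retained — module ids encode the split lineage.
Association tests compare a module's propagation scores against the full
network (module included in the reference, matching the procedure
literally; module-vs-complement is a flag) with a one-sided "greater"
Wilcoxon rank-sum. Because module-in-reference creates structural ties,
scipy's exact method (which ignores ties) is not used; instead a tie-aware
exact null is computed by a counting DP over doubled midranks whenever the
combined sample has ≤ 60 observations, with the tie-corrected normal
approximation above that. BH adjustment runs across modules within each
trait (per-trait, not jointly across traits; a flag switches).
A module is associated iff adjusted p < 0.05 *and* it contains at least
one trait seed gene.

## Cross-species integration

Mouse phenotypes (≥ 10 seed genes each) are ranked by Euclidean distance
between z-scored profiles; k = 20 is the default in the clustering
context and k = 10 for gene prediction (the recovery optimum). A
distance-threshold strategy, a Jaccard-overlap strategy and a seeded
random strategy exist for ablations. For gene ranking, the disease's seed
genes are removed from every selected phenotype's seeds (hold-out
hygiene; emptied phenotypes are dropped), propagation is re-run, and each
gene's scores are combined by geometric mean — scores, not ranks, are
averaged, then ranked, with zeros floored at machine epsilon and ties
broken lexicographically by gene id for determinism. A seed-count
baseline (how often a gene appears as a remaining seed) is provided for
comparison.

## Expression model

Expression rows (genes) are centered and scaled across cell types, so only
the relative pattern matters. Cell types are selected by per-cell-type
two-group ANOVA (positives vs all other genes) at p < 0.01; a logistic
regression on the selected cell types (L2 λ = 1e-4, purely a separation
guard) is fit on a 90% split and evaluated on the held-out 10% of
positives and 10% of other genes. Class imbalance is left unweighted.

## Prioritization model

Per disease, three features over all network genes: `prop` = 1 −
permutation p (seeds = the round's training genes), `mp` = 1 − normalized
geometric-mean rank from the 10 phenotypes nearest to the training-gene
profile (training genes held out of phenotype seeds), `expr` = the
expression-model score. Features are oriented so higher = better before
per-disease min–max scaling (constant columns map to zeros with a
warning). Training pools floor(n_seeds/5) disjoint 5-gene rounds per
training disease — each seed gene is used exactly once as a training gene —
with the remaining seeds as positives and 150 sampled non-associated genes
per round as negatives, into a single logistic fit (unpenalized maximum
likelihood; ridge λ = 1e-6 fallback under separation). Negative sampling
excludes only the disease's own seeds by default. Evaluation repeats
train/test splits (10 rounds by default), samples up to 1,000 control
genes, and reports PR AUC (average precision), AUROC, and partial AUROC
over specificity 0.95–1.0 with McClish standardization (chance = 0.5,
perfect = 1.0). Final rankings use all seed genes for the features and
exclude them from the candidate list (top 100 by default).

## Preranked GSEA

The enrichment score is the maximum deviation of the weighted KS running
sum (hits add |score|^w normalized over the set's in-list scores, default
w = 1; misses subtract 1/(N − N_hit)); sets concentrated at the top give
positive ES. The null permutes gene labels (random same-size sets);
p-values use the same-sign null with the add-one convention, so the floor
is 1/(n_same_sign + 1) — at or above 1/(B+1). NES divides ES by the mean
|null ES| of the same sign; BH runs across retained sets (max size 2,000).
With heavily skewed score vectors (e.g. logistic probabilities) the
weighted statistic saturates — any set containing one early heavy gene
scores near 1 because hit increments are normalized within the set — so
significance testing of such rankings should use the unweighted statistic
(w = 0), which is how the planted-enrichment validation runs.

## Synthetic worlds

The generator is a stochastic block model: `n_modules` blocks of
`module_size` genes wired at `p_in`, everything else (including background
genes) at `p_out`; edge weights are Uniform(0.4, 1), mimicking confidence
scores above a 0.4 inclusion threshold. Defaults: 300 genes, ten 20-gene
modules, p_in = 0.30, p_out = 0.02 — dense modules on a sparse background,
a desk-scale stand-in for an interactome with 19k nodes. Human traits
draw 4–12 seeds (the real per-disease range of 2–42 scaled to the smaller
world), mouse phenotypes 10–16 (the ≥ 10 filter is enforced), with 10% of
seeds drawn uniformly outside the trait's generating module(s) as noise.
A quarter of human traits span two adjacent modules to emulate
multi-systemic disorders; organ labels are assigned per module, so traits
sharing a module share an organ. Options force disjoint seeds between
same-module traits (isolating network signal from gene overlap), raise
mouse seed noise (emulating the diffuse overlap of a 3,500-phenotype
catalogue), or add background hubs for degree heterogeneity (off by
default; no calibration target exists for the real network's hub bias).
All randomness flows from one integer seed through spawned generator
streams, so worlds are byte-identical given the same configuration.

**Expression generator.** Baseline Normal(5, 1) clipped at zero. Genes of
the designated disease modules (the first three human-trait modules by
default) receive a zero-sum contrast over the signal cell types:
+effect·SD in all but the last signal cell type and −(s−1)·effect in the
last. The zero row-sum confines the planted relative-expression signal to
the signal cell types after per-gene centering — mirroring disease genes
whose relative expression is highest in the relevant cell types and lowest
elsewhere — and keeps the other cell types exactly null, so the ANOVA
false-selection rate equals the nominal alpha (≈ 0.17 expected false
cell types at alpha 0.01 over 17 nulls; exact recovery of the planted
trio is therefore a high-probability, not certain, event per world).

**What the worlds do not model.** Realistic interactome topology
(scale-free degree structure, cliquish complexes of varying density),
ontology hierarchies of phenotype terms, evidence-score heterogeneity, and
tissue-specific networks. Passing tests demonstrate the machinery is
correct and the statistical logic sound under the planted model, not that
effect sizes transfer to real databases.

## Validation sizes and numerical choices

Validation runs use worlds of 150–1,000 genes, permutation counts of
99–999 and bootstrap counts of 20–2,000, chosen so each check carries the
statistical resolution its claim needs; library defaults keep the larger
values (B = 1000 permutations, 2,000 bootstrap replicates). The
random-phenotype null check runs on a 1,000-gene world because at 300
genes the phenotype seed genes make up a large share of the negatives and
the hold-out removal depresses the null AUROC below chance — an artifact
of scale, absent in a 19k-node network. Tie-breaks are lexicographic
everywhere a rank is emitted; all stochastic entry points take an explicit
seed and are covered by determinism tests.

## Known limitations

- Identifiers are opaque strings; no ortholog or ID mapping (inputs are
  assumed pre-mapped, as the real pipeline's were).
- The Wilcoxon module test treats overlapping samples (module within the
  full network) as independent, as the source procedure does; the
  complement reference is available where that bothers the analyst.
- The geometric mean is sensitive to zero scores on disconnected
  components; the epsilon floor preserves ordering but compresses
  magnitude information for unreachable genes.
- PR AUC (average precision) is upward-biased for very small evaluation
  sets; comparisons should use equal-size designs, as the evaluation
  routines do.
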