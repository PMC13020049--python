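"""Cross-species integration: select model-organism phenotypes nearest to a
disease, aggregate their propagation scores into a gene ranking, and
benchmark disease-gene recovery.

For each disease, mouse phenotypes are ranked by Euclidean distance between
z-scored propagation profiles (or by seed-gene Jaccard distance, or
randomly as a control). The disease's known genes are removed from the
selected phenotypes' seed sets, propagation is re-run, and each gene's
scores across the selected phenotypes are combined by geometric mean —
genes near *all* selected phenotypes rank highest, and held-out disease
genes recoverable this way validate the cross-species transfer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError, SeedError
from .io import TraitSeedSet
from .metrics import auroc
from .network import InteractionNetwork
from .propagation import (NetworkPropagator, PropagationConfig,
                          PropagationProfile, zscore_profile)

logger = logging.getLogger(__name__)

__all__ = ["PhenotypeSelection", "AggregatedRanking", "select_nearest_phenotypes",
           "holdout_aggregate_ranking", "benchmark_gene_recovery",
           "selection_robustness"]

STRATEGIES = ("propagation_topk", "propagation_threshold", "jaccard_topk", "random")


@dataclass
class PhenotypeSelection:
    """Ordered phenotypes selected for one disease, with their distances."""

    disease_id: str
    selected: list[tuple[str, float]]  # (phenotype_id, distance), ascending
    strategy: str
    k: int | None = None
    distance_cutoff: float | None = None

    @property
    def phenotype_ids(self) -> list[str]:
        return [p for p, _ in self.selected]


@dataclass
class AggregatedRanking:
    """Per-gene aggregate score and rank for one disease."""

    disease_id: str
    genes: tuple[str, ...]
    scores: np.ndarray
    ranks: np.ndarray  # 1 = best; ties broken lexicographically by gene id
    aggregation: str = "geometric_mean"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores,
                             "rank": self.ranks}).sort_values("rank")

    def rank_of(self, gene: str) -> int:
        return int(self.ranks[self.genes.index(gene)])


def _profile_distances(disease_profile: PropagationProfile,
                       mouse_profiles: Sequence[PropagationProfile]) -> np.ndarray:
    zd = zscore_profile(disease_profile)
    out = np.empty(len(mouse_profiles))
    for i, mp in enumerate(mouse_profiles):
        if mp.nodes != disease_profile.nodes:
            raise InputError("profiles must share the node set")
        out[i] = np.linalg.norm(zd - zscore_profile(mp))
    return out


def select_nearest_phenotypes(disease_profile: PropagationProfile,
                              mouse_profiles: Sequence[PropagationProfile],
                              k: int = 20,
                              strategy: str = "propagation_topk",
                              distance_cutoff: float | None = None,
                              disease_seeds: frozenset[str] | None = None,
                              mouse_traits: Sequence[TraitSeedSet] | None = None,
                              rng_seed: int = 0) -> PhenotypeSelection:
    """Select the mouse phenotypes nearest to a disease.

    Strategies: 'propagation_topk' (k smallest Euclidean distances between
    z-scored profiles; k=20 in the clustering context, k=10 for gene
    prediction), 'propagation_threshold' (all within ``distance_cutoff``),
    'jaccard_topk' (k smallest seed-overlap Jaccard distances; requires
    ``disease_seeds`` and ``mouse_traits``), 'random' (k uniform, seeded).
    Ties are broken by phenotype id for determinism.
    """
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}")
    ids = [p.trait_id for p in mouse_profiles]
    if strategy.startswith("propagation") or strategy == "random":
        dists = _profile_distances(disease_profile, mouse_profiles)
    if strategy == "jaccard_topk":
        if disease_seeds is None or mouse_traits is None:
            raise InputError("jaccard_topk requires disease_seeds and mouse_traits")
        seed_map = {t.trait_id: t.seed_genes for t in mouse_traits}
        dists = np.array([1.0 - len(disease_seeds & seed_map[i]) / len(disease_seeds | seed_map[i])
                          for i in ids])
    order = sorted(range(len(ids)), key=lambda i: (dists[i], ids[i]))
    if strategy == "propagation_threshold":
        if distance_cutoff is None:
            raise InputError("propagation_threshold requires distance_cutoff")
        chosen = [i for i in order if dists[i] <= distance_cutoff]
    elif strategy == "random":
        if k > len(ids):
            raise InputError(f"k={k} exceeds {len(ids)} mouse phenotypes")
        rng = np.random.default_rng(rng_seed)
        picked = set(rng.choice(len(ids), size=k, replace=False).tolist())
        chosen = [i for i in order if i in picked]
    else:
        if k > len(ids):
            raise InputError(f"k={k} exceeds {len(ids)} mouse phenotypes")
        chosen = order[:k]
    return PhenotypeSelection(disease_profile.trait_id,
                              [(ids[i], float(dists[i])) for i in chosen],
                              strategy,
                              k=None if strategy == "propagation_threshold" else k,
                              distance_cutoff=distance_cutoff)


def _rank_descending(genes: Sequence[str], scores: np.ndarray) -> np.ndarray:
    order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
    ranks = np.empty(len(genes), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def holdout_aggregate_ranking(network: InteractionNetwork,
                              disease: TraitSeedSet,
                              selection: PhenotypeSelection,
                              mouse_traits: Sequence[TraitSeedSet],
                              config: PropagationConfig | None = None,
                              aggregation: str = "geometric_mean") -> AggregatedRanking:
    """Rank genes by aggregated propagation from the selected phenotypes.

    The disease's seed genes are removed from every selected phenotype's
    seed set before re-propagating (hold-out hygiene); phenotypes left
    without seeds are dropped with a warning. 'geometric_mean' combines a
    gene's scores as exp(mean log score) (zeros floored at machine epsilon);
    'seed_count' instead counts how often the gene appears as a remaining
    seed across selected phenotypes.
    """
    if not selection.selected:
        raise InputError("empty phenotype selection")
    config = config or PropagationConfig()
    trait_map = {t.trait_id: t for t in mouse_traits}
    holdout_seed_sets = []
    for pid in selection.phenotype_ids:
        seeds = trait_map[pid].seed_genes - disease.seed_genes
        if not seeds:
            logger.warning("phenotype %s left without seeds after hold-out; dropped", pid)
            continue
        holdout_seed_sets.append((pid, seeds))
    if not holdout_seed_sets:
        raise SeedError("all selected phenotypes lost their seeds after hold-out")

    genes = network.nodes
    if aggregation == "seed_count":
        counts = np.zeros(len(genes))
        idx = {g: i for i, g in enumerate(genes)}
        for _, seeds in holdout_seed_sets:
            for g in seeds:
                if g in idx:
                    counts[idx[g]] += 1
        agg = counts
    elif aggregation == "geometric_mean":
        prop = NetworkPropagator(**vars(config)).fit(network)
        S = prop.transform([seeds for _, seeds in holdout_seed_sets])  # (k, n)
        floor = np.finfo(float).tiny
        n_floored = int((S <= floor).sum())
        if n_floored:
            logger.info("floored %d zero propagation score(s)", n_floored)
        agg = np.exp(np.log(np.maximum(S, floor)).mean(axis=0))
    else:
        raise InputError(f"unknown aggregation {aggregation!r}")
    ranks = _rank_descending(genes, agg)
    return AggregatedRanking(disease.trait_id, genes, agg, ranks, aggregation)


def _disease_auroc(ranking: AggregatedRanking, disease: TraitSeedSet) -> float:
    y = np.array([g in disease.seed_genes for g in ranking.genes])
    return auroc(y, ranking.scores)


def benchmark_gene_recovery(diseases: Sequence[TraitSeedSet],
                            mouse_traits: Sequence[TraitSeedSet],
                            network: InteractionNetwork,
                            config: PropagationConfig | None = None,
                            strategies: Sequence[str] = ("propagation_topk", "random"),
                            k: int = 10,
                            distance_cutoff: float | None = None,
                            aggregation: str = "geometric_mean",
                            rng_seed: int = 0) -> dict:
    """AUROC of held-out disease-gene recovery per disease and strategy.

    Positives are the disease's own seed genes (excluded from mouse seeds
    before propagation); negatives are all other network genes. Returns a
    dict with a per-disease AUROC table and two-sample t-tests between the
    first strategy and each other one.
    """
    config = config or PropagationConfig()
    prop = NetworkPropagator(**vars(config)).fit(network)
    mouse_profiles = prop.profiles(mouse_traits)
    rows = []
    for d_idx, disease in enumerate(diseases):
        disease_profile = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
        for strategy in strategies:
            sel = select_nearest_phenotypes(
                disease_profile, mouse_profiles, k=k, strategy=strategy,
                distance_cutoff=distance_cutoff,
                disease_seeds=disease.seed_genes, mouse_traits=mouse_traits,
                rng_seed=rng_seed + d_idx)
            ranking = holdout_aggregate_ranking(network, disease, sel,
                                                mouse_traits, config, aggregation)
            rows.append({"disease_id": disease.trait_id, "strategy": strategy,
                         "auroc": _disease_auroc(ranking, disease)})
    table = pd.DataFrame(rows)
    tests = {}
    base = table[table["strategy"] == strategies[0]]["auroc"].to_numpy()
    for other in strategies[1:]:
        vals = table[table["strategy"] == other]["auroc"].to_numpy()
        t2 = stats.ttest_ind(base, vals)
        paired = stats.ttest_rel(base, vals, alternative="greater")
        tests[other] = {"t_two_sample": float(t2.statistic), "p_two_sample": float(t2.pvalue),
                        "t_paired_greater": float(paired.statistic),
                        "p_paired_greater": float(paired.pvalue)}
    return {"auroc_table": table, "tests": tests}


def selection_robustness(diseases: Sequence[TraitSeedSet],
                         mouse_traits: Sequence[TraitSeedSet],
                         network: InteractionNetwork,
                         config: PropagationConfig | None = None,
                         removal_fractions: Sequence[float] = (0.6, 0.8),
                         n_repeats: int = 10,
                         k: int = 20,
                         rng_seed: int = 0) -> pd.DataFrame:
    """Stability of phenotype selection under disease-seed removal.

    For each repeat, the given fraction of a disease's seed genes is
    removed, selection is redone by propagation and by Jaccard overlap, and
    stability is the fraction of the original top-k retained. Returns a
    tidy table (disease, fraction, repeat, strategy, stability); diseases
    left with no seeds for a fraction are skipped with a note.
    """
    config = config or PropagationConfig()
    prop = NetworkPropagator(**vars(config)).fit(network)
    mouse_profiles = prop.profiles(mouse_traits)
    rng = np.random.default_rng(rng_seed)

    def select_both(seeds: frozenset[str], disease_id: str):
        profile = prop.propagate(seeds, trait_id=disease_id)
        by_prop = select_nearest_phenotypes(profile, mouse_profiles, k=k,
                                            strategy="propagation_topk")
        by_jac = select_nearest_phenotypes(profile, mouse_profiles, k=k,
                                           strategy="jaccard_topk",
                                           disease_seeds=seeds,
                                           mouse_traits=mouse_traits)
        return set(by_prop.phenotype_ids), set(by_jac.phenotype_ids)

    rows = []
    for disease in diseases:
        orig_prop, orig_jac = select_both(disease.seed_genes, disease.trait_id)
        seeds_list = sorted(disease.seed_genes)
        for frac in removal_fractions:
            n_keep = len(seeds_list) - int(round(frac * len(seeds_list)))
            if n_keep < 1:
                logger.info("skipping %s at fraction %.2f (no seeds left)",
                            disease.trait_id, frac)
                continue
            for rep in range(n_repeats):
                if frac == 0:
                    kept = frozenset(seeds_list)
                else:
                    kept = frozenset(rng.choice(seeds_list, size=n_keep,
                                                replace=False).tolist())
                new_prop, new_jac = select_both(kept, disease.trait_id)
                rows.append({"disease_id": disease.trait_id, "fraction": frac,
                             "repeat": rep, "strategy": "propagation",
                             "stability": len(new_prop & orig_prop) / k})
                rows.append({"disease_id": disease.trait_id, "fraction": frac,
                             "repeat": rep, "strategy": "jaccard",
                             "stability": len(new_jac & orig_jac) / k})
    return pd.DataFrame(rows)
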