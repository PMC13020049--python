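"""Protein-module detection and module–trait association.

The network is partitioned with Walktrap community detection (short random
walks tend to stay inside densely connected modules). Because functional
complexes are expected to be small, any module larger than ``max_size``
genes is recursively re-clustered as an induced subgraph, up to
``max_rounds`` rounds; oversized modules that stop splitting are retained.
A module is associated with a trait when the trait's propagation scores are
significantly higher inside the module than over the full network (one-
sided Wilcoxon rank-sum, BH-adjusted across modules within each trait) and
the module contains at least one of the trait's seed genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .io import TraitSeedSet
from .network import InteractionNetwork
from .propagation import PropagationProfile

logger = logging.getLogger(__name__)

__all__ = ["ModulePartition", "ModuleTraitAssociation", "recursive_walktrap",
           "associate_modules", "overrepresentation_test",
           "module_composition_fractions"]


@dataclass
class ModulePartition:
    """Exhaustive, disjoint gene → module assignment with lineage."""

    assignments: dict[str, str]  # gene -> module id (lineage-encoded, e.g. "2.0.1")
    round_created: dict[str, int]  # module id -> recursion round (1-based)
    parents: dict[str, str | None]  # module id -> parent module id

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gene, mod in self.assignments.items():
            out.setdefault(mod, []).append(gene)
        return {m: sorted(g) for m, g in sorted(out.items())}

    def sizes(self) -> dict[str, int]:
        return {m: len(g) for m, g in self.modules().items()}

    def depth(self, module_id: str) -> int:
        return self.round_created[module_id]

    def validate(self, nodes: Iterable[str]) -> None:
        nodes = set(nodes)
        assigned = set(self.assignments)
        if assigned != nodes:
            raise InputError("partition is not exhaustive over network nodes")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "module_id": m, "round": self.round_created[m]}
                for g, m in sorted(self.assignments.items())]
        return pd.DataFrame(rows)


def _walktrap_membership(subgraph, steps: int) -> list[int]:
    dendro = subgraph.community_walktrap(weights="weight", steps=steps)
    return dendro.as_clustering().membership


def recursive_walktrap(network: InteractionNetwork, max_size: int = 20,
                       max_rounds: int = 5, steps: int = 4) -> ModulePartition:
    """Recursively partition the network into modules of <= ``max_size`` genes.

    Connected components are clustered independently. Modules still larger
    than ``max_size`` after ``max_rounds`` rounds (or that refuse to split)
    are retained unsplit. Module ids encode lineage ("<comp>.<i>.<j>...").
    """
    assignments: dict[str, str] = {}
    round_created: dict[str, int] = {}
    parents: dict[str, str | None] = {}

    def finalize(genes: Sequence[str], module_id: str, rnd: int, parent: str | None):
        for g in genes:
            assignments[g] = module_id
        round_created[module_id] = rnd
        parents[module_id] = parent

    def split(genes: list[str], prefix: str, rnd: int, parent: str | None):
        sub = network.subgraph(genes)
        if sub.n_nodes < 2 or sub.n_edges == 0:
            finalize(genes, prefix, rnd, parent)
            return
        membership = _walktrap_membership(sub.to_igraph(), steps)
        groups: dict[int, list[str]] = {}
        for gene, m in zip(sub.nodes, membership):
            groups.setdefault(m, []).append(gene)
        if len(groups) == 1:  # refused to split; retain as-is
            finalize(genes, prefix, rnd, parent)
            return
        for child_idx, members in enumerate(groups[m] for m in sorted(groups)):
            child_id = f"{prefix}.{child_idx}"
            if len(members) > max_size and rnd < max_rounds:
                split(members, child_id, rnd + 1, prefix)
            else:
                finalize(members, child_id, rnd, prefix)

    for comp_idx, comp in enumerate(network.connected_components()):
        split(sorted(comp), str(comp_idx), 1, None)

    partition = ModulePartition(assignments, round_created, parents)
    partition.validate(network.nodes)
    return partition


def _exact_ranksum_greater_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact one-sided (greater) rank-sum p-value, tie-aware.

    Computes P(rank-sum of a random |x|-subset >= observed) over all
    subsets of the combined sample via a counting DP on doubled midranks
    (midranks are multiples of 1/2, so doubling gives integers). Handles
    the ties that arise when the module is included in the reference.
    Feasible only for small combined samples.
    """
    from math import comb

    combined = np.concatenate([x, y])
    ranks2 = np.rint(2 * stats.rankdata(combined)).astype(int)
    n, n1 = combined.size, x.size
    obs2 = int(np.rint(2 * stats.rankdata(combined)[:n1].sum()))
    max_sum = int(ranks2.sum())
    # ways[j][s] = number of size-j subsets with doubled-rank sum s
    ways = [np.zeros(max_sum + 1, dtype=object) for _ in range(n1 + 1)]
    ways[0][0] = 1
    for r in ranks2:
        for j in range(n1, 0, -1):
            prev = ways[j - 1]
            if prev.any():
                ways[j][r:] = ways[j][r:] + prev[:max_sum + 1 - r]
    dist = ways[n1]
    total = comb(n, n1)
    count = int(sum(dist[obs2:]))
    return count / total


@dataclass
class ModuleTraitAssociation:
    """Statistical link between one protein module and one trait."""

    module_id: str
    trait_id: str
    wilcoxon_p: float
    adjusted_p: float
    n_trait_seeds_in_module: int
    associated: bool


def associate_modules(partition: ModulePartition,
                      profiles: Sequence[PropagationProfile],
                      traits: Sequence[TraitSeedSet],
                      alpha: float = 0.05,
                      reference: str = "full",
                      exact_total_max: int = 60) -> list[ModuleTraitAssociation]:
    """Associate modules with traits via one-sided Wilcoxon rank-sum tests.

    For each (trait, module) pair the module's propagation scores are tested
    against the reference distribution — all network nodes by default
    (``reference='full'``), or the module's complement
    (``reference='complement'``) — with alternative 'greater'. P-values are
    BH-adjusted across modules within each trait; a module is associated iff
    adjusted p < alpha and it contains >= 1 of the trait's seed genes.
    Modules of size < 2 are skipped. The tie-aware exact null is enumerated
    when the combined sample has at most ``exact_total_max`` observations;
    the tie-corrected normal approximation is used above that.
    """
    trait_by_id = {t.trait_id: t for t in traits}
    modules = partition.modules()
    results: list[ModuleTraitAssociation] = []
    for profile in profiles:
        trait = trait_by_id.get(profile.trait_id)
        if trait is None:
            raise InputError(f"no TraitSeedSet for profile {profile.trait_id!r}")
        scores = profile.as_series()
        rows = []
        for module_id, genes in modules.items():
            if len(genes) < 2:
                logger.info("skipping module %s (size < 2)", module_id)
                continue
            x = scores.loc[genes].to_numpy()
            y = (scores.to_numpy() if reference == "full"
                 else scores.drop(index=genes).to_numpy())
            if x.size + y.size <= exact_total_max:
                p = _exact_ranksum_greater_p(x, y)
            else:
                p = stats.mannwhitneyu(x, y, alternative="greater",
                                       method="asymptotic").pvalue
            rows.append((module_id, float(p), len(set(genes) & trait.seed_genes)))
        pvals = [r[1] for r in rows]
        adj = multipletests(pvals, method="fdr_bh")[1] if rows else []
        for (module_id, p, n_seeds), q in zip(rows, adj):
            results.append(ModuleTraitAssociation(
                module_id, profile.trait_id, p, float(q), n_seeds,
                associated=bool(q < alpha and n_seeds >= 1)))
    return results


def overrepresentation_test(module_genes: Iterable[str],
                            gene_sets: Mapping[str, Iterable[str]],
                            universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    Returns (set_name, set_size, overlap, pvalue, qvalue) with BH across
    sets. ``module_genes`` must be a subset of ``universe``.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    module = set(module_genes)
    if not module <= universe:
        raise InputError("module genes must be a subset of the universe")
    M, n = len(universe), len(module)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        k = len(members & module)
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n))
        rows.append({"set_name": name, "set_size": len(members),
                     "overlap": k, "pvalue": p})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["qvalue"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df


def module_composition_fractions(partition: ModulePartition,
                                 candidate_genes: Mapping[str, Iterable[str]] | Iterable[str],
                                 ciliary_genes: Iterable[str],
                                 known_genes: Iterable[str],
                                 display_min: float = 0.6) -> pd.DataFrame:
    """Per-module fraction of candidate, pathway-class and known disease genes.

    ``candidate_genes`` may be a per-trait mapping (aggregated across
    traits) or a flat collection. Modules are flagged for display when any
    fraction exceeds ``display_min``.
    """
    if isinstance(candidate_genes, Mapping):
        candidates = {g for genes in candidate_genes.values() for g in genes}
    else:
        candidates = set(candidate_genes)
    ciliary, known = set(ciliary_genes), set(known_genes)
    rows = []
    for module_id, genes in partition.modules().items():
        size = len(genes)
        gset = set(genes)
        fracs = {
            "frac_candidate": len(gset & candidates) / size,
            "frac_ciliary": len(gset & ciliary) / size,
            "frac_known": len(gset & known) / size,
        }
        rows.append({"module_id": module_id, "size": size, **fracs,
                     "display": any(v > display_min for v in fracs.values())})
    return pd.DataFrame(rows)
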