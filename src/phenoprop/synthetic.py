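"""Planted-truth synthetic worlds for benchmarking the pipeline.

The generator emulates the statistical structure of the real inputs (a PPI
network with dense functional modules, human-trait and mouse-phenotype seed
sets drawn from shared modules with noise, organ annotations aligned with
module membership, and an expression matrix with cell-type-specific signal)
so that every downstream stage has a known answer. The graph family is a
planted-partition (stochastic block) model: each of ``n_modules`` blocks of
``module_size`` genes is wired internally with probability ``p_in`` and
externally with ``p_out``; leftover genes form background wired at ``p_out``.

All randomness flows from a single integer seed through a splittable
generator; the graph, trait and expression stages each get a derived stream,
so identical configurations reproduce byte-identical worlds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError
from .expression import ExpressionMatrix
from .io import ORGAN_PHENOTYPES, TraitSeedSet, write_network
from .network import InteractionNetwork

__all__ = ["SyntheticWorldConfig", "SyntheticWorld", "generate_world",
           "generate_expression", "write_world"]

BACKGROUND = -1


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Study conditions of a synthetic world.

    Defaults describe a 300-gene world with ten 20-gene modules (p_in=0.30,
    p_out=0.02), eight human traits drawing 4–12 seeds and twenty mouse
    phenotypes drawing 10–16 seeds, with 10% of seeds drawn outside the
    trait's generating module(s). Mouse phenotypes keep the minimum of ten
    seed genes used to exclude single-disease mouse models.
    """

    n_genes: int = 300
    n_modules: int = 10
    module_size: int = 20
    p_in: float = 0.30
    p_out: float = 0.02
    n_human_traits: int = 8
    n_mouse_traits: int = 20
    human_seeds_range: tuple[int, int] = (4, 12)
    mouse_seeds_min: int = 10
    mouse_seeds_max: int = 16
    seed_noise_frac: float = 0.10
    mouse_seed_noise_frac: float | None = None  # defaults to seed_noise_frac
    multisystemic_frac: float = 0.25  # fraction of human traits spanning two modules
    traits_per_module: Mapping[int, Sequence[int]] | None = None  # human trait -> modules
    mouse_traits_per_module: Mapping[int, Sequence[int]] | None = None
    organ_per_module: Mapping[int, str] | None = None
    disjoint_same_module_seeds: bool = False
    n_hubs: int = 0  # background hub genes adding degree heterogeneity
    hub_edge_prob: float = 0.2
    weight_range: tuple[float, float] = (0.4, 1.0)
    n_celltypes: int = 20
    signal_celltypes: int = 3
    expression_effect_size: float = 2.0
    n_signal_modules: int = 3
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError(
                f"{self.n_modules} modules of {self.module_size} genes exceed "
                f"n_genes={self.n_genes}")
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ConfigurationError("require 0 <= p_out < p_in <= 1")
        if self.mouse_seeds_min < 10:
            raise ConfigurationError("mouse_seeds_min must be >= 10")
        if not (0.0 <= self.seed_noise_frac <= 1.0):
            raise ConfigurationError("seed_noise_frac must be in [0, 1]")
        lo, hi = self.human_seeds_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("invalid human_seeds_range")
        if self.signal_celltypes > self.n_celltypes:
            raise ConfigurationError("signal_celltypes must be <= n_celltypes")


@dataclass
class SyntheticWorld:
    """A generated world with its full planted truth."""

    config: SyntheticWorldConfig
    network: InteractionNetwork
    module_truth: dict[str, int]  # gene -> module id (BACKGROUND for background)
    human_traits: list[TraitSeedSet]
    mouse_traits: list[TraitSeedSet]
    organ_annotations: dict[str, frozenset[str]]
    trait_modules: dict[str, tuple[int, ...]]  # trait -> generating module ids
    expression: ExpressionMatrix | None = None
    signal_celltype_names: tuple[str, ...] = ()
    signal_genes: frozenset[str] = frozenset()

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_truth.items()
                      if m == module and g in self.network)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _planted_partition_graph(cfg: SyntheticWorldConfig,
                             rng: np.random.Generator) -> tuple[InteractionNetwork, dict[str, int]]:
    n = cfg.n_genes
    genes = _gene_names(n)
    labels = np.full(n, BACKGROUND, dtype=int)
    for m in range(cfg.n_modules):
        labels[m * cfg.module_size:(m + 1) * cfg.module_size] = m
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] != BACKGROUND)
    prob = np.where(same, cfg.p_in, cfg.p_out)
    draw = rng.random((n, n))
    iu, ju = np.triu_indices(n, k=1)
    hit = draw[iu, ju] < prob[iu, ju]
    ei, ej = iu[hit], ju[hit]
    lo, hi = cfg.weight_range
    weights = rng.uniform(lo, hi, size=ei.size)
    edges = [(genes[i], genes[j], float(w)) for i, j, w in zip(ei, ej, weights)]
    if cfg.n_hubs > 0:
        background = [i for i in range(n) if labels[i] == BACKGROUND]
        hubs = background[:cfg.n_hubs]
        for h in hubs:
            targets = np.flatnonzero(rng.random(n) < cfg.hub_edge_prob)
            w_extra = rng.uniform(lo, hi, size=targets.size)
            edges.extend((genes[h], genes[t], float(w))
                         for t, w in zip(targets, w_extra) if t != h)
    network = InteractionNetwork.from_edges(edges)
    truth = {genes[i]: int(labels[i]) for i in range(n)}
    return network, truth


def _default_assignment(n_traits: int, n_modules: int, multi_frac: float) -> dict[int, tuple[int, ...]]:
    n_multi = int(round(multi_frac * n_traits))
    out: dict[int, tuple[int, ...]] = {}
    for i in range(n_traits):
        m = i % n_modules
        if i < n_multi:  # multi-systemic traits span two adjacent modules
            out[i] = (m, (m + 1) % n_modules)
        else:
            out[i] = (m,)
    return out


def _draw_trait_seeds(pool_by_module: dict[int, list[str]],
                      modules: tuple[int, ...],
                      all_genes: list[str],
                      k: int, noise_frac: float,
                      rng: np.random.Generator,
                      used: dict[int, set[str]] | None) -> frozenset[str]:
    module_pool: list[str] = []
    for m in modules:
        pool = pool_by_module[m]
        if used is not None:
            pool = [g for g in pool if g not in used[m]]
        module_pool.extend(pool)
    module_pool = sorted(set(module_pool))
    module_set = {g for m in modules for g in pool_by_module[m]}
    outside_pool = [g for g in all_genes if g not in module_set]

    n_noise = int(round(noise_frac * k))
    n_module = min(k - n_noise, len(module_pool))
    n_noise = min(k - n_module, len(outside_pool))
    seeds = set()
    if n_module:
        seeds.update(rng.choice(module_pool, size=n_module, replace=False).tolist())
    if n_noise:
        seeds.update(rng.choice(outside_pool, size=n_noise, replace=False).tolist())
    if used is not None:
        for m in modules:
            used[m].update(seeds)
    return frozenset(seeds)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate a planted-partition world with traits, organs and expression.

    Deterministic given ``config.rng_seed``; raises ConfigurationError for
    infeasible configurations.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    rng_graph, rng_traits, rng_expr = (np.random.default_rng(s) for s in ss.spawn(3))

    network, truth = _planted_partition_graph(config, rng_graph)
    all_genes = [g for g in sorted(truth) if g in network]
    pool_by_module = {m: [g for g in all_genes if truth[g] == m]
                      for m in range(config.n_modules)}

    organ_map = dict(config.organ_per_module or {
        m: ORGAN_PHENOTYPES[m % len(ORGAN_PHENOTYPES)] for m in range(config.n_modules)})

    human_assign = dict(config.traits_per_module or _default_assignment(
        config.n_human_traits, config.n_modules, config.multisystemic_frac))
    mouse_assign = dict(config.mouse_traits_per_module or _default_assignment(
        config.n_mouse_traits, config.n_modules, 0.0))

    used: dict[int, set[str]] | None = None
    if config.disjoint_same_module_seeds:
        used = {m: set() for m in range(config.n_modules)}

    mouse_noise = (config.seed_noise_frac if config.mouse_seed_noise_frac is None
                   else config.mouse_seed_noise_frac)

    human_traits: list[TraitSeedSet] = []
    organ_annotations: dict[str, frozenset[str]] = {}
    trait_modules: dict[str, tuple[int, ...]] = {}
    lo, hi = config.human_seeds_range
    for i in range(config.n_human_traits):
        modules = tuple(human_assign[i])
        k = int(rng_traits.integers(lo, hi + 1))
        seeds = _draw_trait_seeds(pool_by_module, modules, all_genes, k,
                                  config.seed_noise_frac, rng_traits, used)
        organs = frozenset(organ_map[m] for m in modules)
        tid = f"disease_{i:02d}"
        human_traits.append(TraitSeedSet(tid, "human", seeds, organs))
        organ_annotations[tid] = organs
        trait_modules[tid] = modules

    mouse_traits: list[TraitSeedSet] = []
    for j in range(config.n_mouse_traits):
        modules = tuple(mouse_assign[j])
        k = int(rng_traits.integers(config.mouse_seeds_min, config.mouse_seeds_max + 1))
        seeds = _draw_trait_seeds(pool_by_module, modules, all_genes, k,
                                  mouse_noise, rng_traits, None)
        tid = f"mp_{j:03d}"
        mouse_traits.append(TraitSeedSet(tid, "mouse", seeds))
        trait_modules[tid] = modules

    world = SyntheticWorld(config, network, truth, human_traits, mouse_traits,
                           organ_annotations, trait_modules)

    signal_modules = sorted({m for t in human_traits for m in trait_modules[t.trait_id]})
    signal_modules = signal_modules[:config.n_signal_modules]
    signal_genes = frozenset(g for m in signal_modules for g in pool_by_module[m])
    expr, signal_ct = generate_expression(
        world, config.n_celltypes, config.signal_celltypes,
        config.expression_effect_size, rng_expr, signal_genes=signal_genes,
        return_signal_celltypes=True)
    world.expression = expr
    world.signal_celltype_names = signal_ct
    world.signal_genes = signal_genes
    return world


def generate_expression(world: SyntheticWorld, n_celltypes: int,
                        signal_celltypes: int, effect_size: float,
                        rng_seed: int | np.random.Generator = 0,
                        signal_genes: frozenset[str] | None = None,
                        return_signal_celltypes: bool = False):
    """Genes × cell-type expression with planted cell-type-specific signal.

    Baseline expression is Normal(5, 1) clipped at zero (nonnegative). Genes
    in the designated disease modules receive a zero-sum contrast over the
    first ``signal_celltypes`` cell types: +``effect_size`` (in baseline-SD
    units) in all but the last signal cell type and a compensating
    −(s−1)·``effect_size`` in the last one. The zero row-sum keeps the
    planted relative-expression signal confined to the signal cell types
    after per-gene centering — mirroring disease genes whose relative
    expression is highest in the relevant cell types and lowest elsewhere.
    Deterministic given ``rng_seed``.
    """
    import pandas as pd

    if signal_celltypes > n_celltypes:
        raise ConfigurationError("signal_celltypes must be <= n_celltypes")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    genes = list(world.network.nodes)
    if signal_genes is None:
        modules = sorted({m for t in world.human_traits
                          for m in world.trait_modules[t.trait_id]})
        modules = modules[:world.config.n_signal_modules]
        signal_genes = frozenset(g for g in genes
                                 if world.module_truth.get(g) in set(modules))
    celltypes = tuple(f"celltype_{c:02d}" for c in range(n_celltypes))
    values = rng.normal(loc=5.0, scale=1.0, size=(len(genes), n_celltypes))
    sig_rows = np.array([g in signal_genes for g in genes])
    if signal_celltypes > 0 and effect_size != 0:
        contrast = np.full(signal_celltypes, effect_size)
        if signal_celltypes > 1:
            contrast[-1] = -(signal_celltypes - 1) * effect_size
        values[np.ix_(sig_rows, np.arange(signal_celltypes))] += contrast
    values = np.clip(values, 0.0, None)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=list(celltypes)))
    if return_signal_celltypes:
        return matrix, celltypes[:signal_celltypes]
    return matrix


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Write network, trait table, organ annotations, expression and truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_network(world.network, outdir / "network.tsv")
    with (outdir / "traits.tsv").open("w", encoding="utf-8") as fh:
        fh.write("gene\ttrait_id\ttrait_class\tsource\tscore\n")
        for trait in [*world.human_traits, *world.mouse_traits]:
            for gene in sorted(trait.seed_genes):
                fh.write(f"{gene}\t{trait.trait_id}\t{trait.trait_class}\tsynthetic\t1.0\n")
    with (outdir / "organs.tsv").open("w", encoding="utf-8") as fh:
        fh.write("trait_id\torgan\n")
        for tid in sorted(world.organ_annotations):
            for organ in sorted(world.organ_annotations[tid]):
                fh.write(f"{tid}\t{organ}\n")
    if world.expression is not None:
        world.expression.data.to_csv(outdir / "expression.tsv", sep="\t",
                                     index_label="gene")
    truth = {
        "config": asdict(world.config),
        "module_truth": world.module_truth,
        "trait_modules": {k: list(v) for k, v in world.trait_modules.items()},
        "signal_celltypes": list(world.signal_celltype_names),
        "signal_genes": sorted(world.signal_genes),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
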