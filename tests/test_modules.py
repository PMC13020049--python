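import math

import numpy as np
import pytest

import phenoprop as pp

from helpers import exact_ranksum_greater_p, random_er_network


def _clique_edges(genes, w=0.9):
    return [(a, b, w) for i, a in enumerate(genes) for b in genes[i + 1:]]


class TestRecursiveWalktrap:
    def test_small_network_finishes_in_round_one(self):
        rng = np.random.default_rng(0)
        net = random_er_network(rng, 15, p=0.3)
        part = pp.recursive_walktrap(net)
        assert max(part.round_created.values()) == 1
        assert set(part.assignments) == set(net.nodes)

    def test_two_cliques_joined_by_one_edge_split(self):
        left = [f"L{i}" for i in range(10)]
        right = [f"R{i}" for i in range(10)]
        edges = _clique_edges(left) + _clique_edges(right) + [("L0", "R0", 0.9)]
        net = pp.InteractionNetwork.from_edges(edges)
        part = pp.recursive_walktrap(net)
        left_mods = {part.assignments[g] for g in left}
        right_mods = {part.assignments[g] for g in right}
        assert len(left_mods) == 1 and len(right_mods) == 1
        assert left_mods != right_mods

    def test_unsplittable_large_module_is_retained(self):
        # A 30-clique never splits: the module stays > max_size at the cap.
        genes = [f"C{i}" for i in range(30)]
        net = pp.InteractionNetwork.from_edges(_clique_edges(genes))
        part = pp.recursive_walktrap(net, max_size=20, max_rounds=5)
        sizes = part.sizes()
        assert max(sizes.values()) == 30

    def test_partition_exhaustive_disjoint_and_bounded(self, world):
        part = pp.recursive_walktrap(world.network, max_size=20, max_rounds=5)
        genes = list(part.assignments)
        assert sorted(genes) == sorted(world.network.nodes)
        for module_id, size in part.sizes().items():
            assert size <= 20 or part.round_created[module_id] >= 5

    def test_disconnected_components_clustered_independently(self):
        a = _clique_edges([f"A{i}" for i in range(5)])
        b = _clique_edges([f"B{i}" for i in range(5)])
        net = pp.InteractionNetwork.from_edges(a + b)
        part = pp.recursive_walktrap(net)
        mods_a = {part.assignments[f"A{i}"] for i in range(5)}
        mods_b = {part.assignments[f"B{i}"] for i in range(5)}
        assert not (mods_a & mods_b)


class TestAssociateModules:
    def _tiny_setup(self, scores, module_genes, seed_genes, all_genes):
        nodes = tuple(sorted(all_genes))
        profile = pp.PropagationProfile(
            "t", nodes, np.array([scores[g] for g in nodes]))
        assignments = {g: ("m1" if g in module_genes else "m0") for g in nodes}
        part = pp.ModulePartition(assignments,
                                  {"m0": 1, "m1": 1}, {"m0": None, "m1": None})
        trait = pp.TraitSeedSet("t", "human", frozenset(seed_genes))
        return part, [profile], [trait]

    def test_pvalue_matches_exact_enumeration(self):
        rng = np.random.default_rng(3)
        all_genes = [f"g{i}" for i in range(12)]
        scores = {g: float(rng.random()) for g in all_genes}
        module = set(all_genes[:4])
        part, profiles, traits = self._tiny_setup(scores, module, {"g0"}, all_genes)
        assoc = {(a.module_id): a for a in pp.associate_modules(part, profiles, traits)}
        x = np.array([scores[g] for g in sorted(module)])
        y = np.array([scores[g] for g in sorted(all_genes)])
        oracle = exact_ranksum_greater_p(x, y)
        assert abs(assoc["m1"].wilcoxon_p - oracle) < 1e-12

    def test_null_module_not_associated(self, world, propagator):
        # a random module drawn from the global distribution is not enriched
        rng = np.random.default_rng(0)
        nodes = list(world.network.nodes)
        module = set(rng.choice(nodes, size=15, replace=False).tolist())
        assignments = {g: ("m1" if g in module else "m0") for g in nodes}
        part = pp.ModulePartition(assignments, {"m0": 1, "m1": 1},
                                  {"m0": None, "m1": None})
        trait = world.human_traits[0]
        profile = propagator.propagate(trait.seed_genes, trait_id=trait.trait_id)
        assoc = [a for a in pp.associate_modules(part, [profile], [trait])
                 if a.module_id == "m1"]
        assert assoc[0].wilcoxon_p > 1e-4  # nowhere near enrichment

    def test_planted_module_is_associated(self, world, propagator):
        part = pp.recursive_walktrap(world.network)
        trait = world.human_traits[-1]  # single-module trait
        module = world.trait_modules[trait.trait_id][0]
        module_genes = set(world.module_genes(module))
        profile = propagator.propagate(trait.seed_genes, trait_id=trait.trait_id)
        assoc = pp.associate_modules(part, [profile], [trait])
        # the detected module holding most of the planted module must be associated
        best = max(part.modules().items(),
                   key=lambda kv: len(set(kv[1]) & module_genes))
        hit = [a for a in assoc if a.module_id == best[0]]
        assert hit[0].associated

    def test_module_without_seed_gene_never_associated(self):
        rng = np.random.default_rng(1)
        all_genes = [f"g{i}" for i in range(30)]
        scores = {g: float(rng.random()) for g in all_genes}
        module = set(all_genes[:10])
        for g in module:  # strongly elevated scores, but no seeds inside
            scores[g] += 10.0
        part, profiles, traits = self._tiny_setup(scores, module, {"g20"}, all_genes)
        assoc = {a.module_id: a for a in pp.associate_modules(part, profiles, traits)}
        assert assoc["m1"].adjusted_p < 0.05
        assert assoc["m1"].n_trait_seeds_in_module == 0
        assert not assoc["m1"].associated


class TestOverrepresentation:
    def test_module_equal_to_set_gets_minimal_tail(self):
        universe = [f"u{i}" for i in range(1000)]
        module = set(universe[:8])
        res = pp.overrepresentation_test(module, {"S": module}, universe)
        from scipy.stats import hypergeom
        expected = float(hypergeom.sf(7, 1000, 8, 8))
        assert abs(res.loc[0, "pvalue"] - expected) < 1e-15
        assert expected == pytest.approx(1 / math.comb(1000, 8), rel=1e-9)

    def test_disjoint_set_is_not_enriched(self):
        universe = [f"u{i}" for i in range(100)]
        res = pp.overrepresentation_test(set(universe[:10]),
                                         {"S": set(universe[50:60])}, universe)
        assert res.loc[0, "pvalue"] > 0.3

    def test_bh_is_monotone_in_p(self):
        rng = np.random.default_rng(4)
        universe = [f"u{i}" for i in range(200)]
        module = set(universe[:20])
        sets = {f"S{k}": set(rng.choice(universe, size=15, replace=False).tolist())
                for k in range(10)}
        res = pp.overrepresentation_test(module, sets, universe)
        res = res.sort_values("pvalue")
        assert res["qvalue"].is_monotonic_increasing


class TestCompositionFractions:
    def test_hand_computed_fractions(self):
        assignments = {"a": "m1", "b": "m1", "c": "m1",
                       "d": "m2", "e": "m2", "f": "m3"}
        part = pp.ModulePartition(assignments, {m: 1 for m in ("m1", "m2", "m3")},
                                  {m: None for m in ("m1", "m2", "m3")})
        out = pp.module_composition_fractions(
            part, candidate_genes={"t": {"a", "d"}},
            ciliary_genes={"a", "b"}, known_genes={"f"})
        out = out.set_index("module_id")
        assert out.loc["m1", "frac_candidate"] == pytest.approx(1 / 3)
        assert out.loc["m1", "frac_ciliary"] == pytest.approx(2 / 3)
        assert out.loc["m3", "frac_known"] == 1.0
        assert bool(out.loc["m3", "display"]) is True
        assert bool(out.loc["m2", "display"]) is False

    def test_display_threshold_default(self):
        import inspect
        sig = inspect.signature(pp.module_composition_fractions)
        assert sig.parameters["display_min"].default == 0.6
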