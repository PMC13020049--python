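import numpy as np
import pytest

import phenoprop as pp
from phenoprop.exceptions import InputError, SeedError


@pytest.fixture(scope="module")
def mouse_world():
    cfg = pp.SyntheticWorldConfig(n_human_traits=6, n_mouse_traits=20,
                                  multisystemic_frac=0.0, rng_seed=8)
    return pp.generate_world(cfg)


@pytest.fixture(scope="module")
def mouse_profiles(mouse_world):
    prop = pp.NetworkPropagator().fit(mouse_world.network)
    return prop, prop.profiles(mouse_world.mouse_traits)


class TestSelection:
    def test_identical_seed_phenotype_ranks_first(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        twin = mouse_world.mouse_traits[0]
        disease_profile = prop.propagate(twin.seed_genes, trait_id="dz")
        sel = pp.select_nearest_phenotypes(disease_profile, profiles, k=5)
        assert sel.selected[0][0] == twin.trait_id
        assert sel.selected[0][1] == pytest.approx(0.0, abs=1e-6)
        assert [d for _, d in sel.selected] == sorted(d for _, d in sel.selected)

    def test_same_module_phenotypes_fill_top_ranks(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        precisions = []
        for disease in mouse_world.human_traits:
            module = mouse_world.trait_modules[disease.trait_id][0]
            same = {t.trait_id for t in mouse_world.mouse_traits
                    if module in mouse_world.trait_modules[t.trait_id]}
            dp = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
            sel = pp.select_nearest_phenotypes(dp, profiles, k=len(same))
            precisions.append(len(set(sel.phenotype_ids) & same) / len(same))
        assert np.mean(precisions) >= 0.9

    def test_k_too_large_raises(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        dp = prop.propagate(mouse_world.human_traits[0].seed_genes)
        with pytest.raises(InputError):
            pp.select_nearest_phenotypes(dp, profiles, k=len(profiles) + 1)

    def test_random_strategy_is_seeded(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        dp = prop.propagate(mouse_world.human_traits[0].seed_genes)
        s1 = pp.select_nearest_phenotypes(dp, profiles, k=5, strategy="random",
                                          rng_seed=3)
        s2 = pp.select_nearest_phenotypes(dp, profiles, k=5, strategy="random",
                                          rng_seed=3)
        assert s1.phenotype_ids == s2.phenotype_ids


class TestAggregatedRanking:
    def test_single_phenotype_equals_own_ranking(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        disease = mouse_world.human_traits[0]
        dp = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
        sel = pp.select_nearest_phenotypes(dp, profiles, k=1)
        rank = pp.holdout_aggregate_ranking(mouse_world.network, disease, sel,
                                            mouse_world.mouse_traits)
        pid = sel.phenotype_ids[0]
        seeds = {t.trait_id: t.seed_genes for t in mouse_world.mouse_traits}[pid]
        own = prop.propagate(seeds - disease.seed_genes)
        assert np.allclose(rank.scores, own.scores)

    def test_geometric_mean_matches_exp_mean_log(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        disease = mouse_world.human_traits[1]
        dp = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
        sel = pp.select_nearest_phenotypes(dp, profiles, k=5)
        rank = pp.holdout_aggregate_ranking(mouse_world.network, disease, sel,
                                            mouse_world.mouse_traits)
        seed_map = {t.trait_id: t.seed_genes for t in mouse_world.mouse_traits}
        per_pheno = np.vstack([
            prop.propagate(seed_map[pid] - disease.seed_genes).scores
            for pid in sel.phenotype_ids])
        oracle = np.exp(np.log(per_pheno).mean(axis=0))
        assert np.abs(rank.scores - oracle).max() < 1e-12
        # AM-GM inequality per gene
        assert (rank.scores <= per_pheno.mean(axis=0) + 1e-15).all()

    def test_aggregation_is_order_invariant(self, mouse_world, mouse_profiles):
        prop, profiles = mouse_profiles
        disease = mouse_world.human_traits[2]
        dp = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
        sel = pp.select_nearest_phenotypes(dp, profiles, k=4)
        rev = pp.PhenotypeSelection(sel.disease_id, sel.selected[::-1],
                                    sel.strategy, k=sel.k)
        r1 = pp.holdout_aggregate_ranking(mouse_world.network, disease, sel,
                                          mouse_world.mouse_traits)
        r2 = pp.holdout_aggregate_ranking(mouse_world.network, disease, rev,
                                          mouse_world.mouse_traits)
        assert np.array_equal(r1.ranks, r2.ranks)

    def test_ranks_are_a_permutation_with_deterministic_ties(self, mouse_world,
                                                             mouse_profiles):
        prop, profiles = mouse_profiles
        disease = mouse_world.human_traits[3]
        dp = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
        sel = pp.select_nearest_phenotypes(dp, profiles, k=3)
        rank = pp.holdout_aggregate_ranking(mouse_world.network, disease, sel,
                                            mouse_world.mouse_traits,
                                            aggregation="seed_count")
        assert sorted(rank.ranks) == list(range(1, len(rank.genes) + 1))
        # ties in seed_count resolve lexicographically by gene id
        frame = rank.as_frame()
        for _, grp in frame.groupby("score"):
            genes = grp.sort_values("rank")["gene"].tolist()
            assert genes == sorted(genes)

    def test_phenotype_consumed_by_holdout_is_dropped(self, mouse_world):
        disease = mouse_world.human_traits[0]
        sub = pp.TraitSeedSet("sub", "mouse",
                              frozenset(list(disease.seed_genes)[:10]))
        sel = pp.PhenotypeSelection(disease.trait_id, [("sub", 0.0)],
                                    "propagation_topk", k=1)
        with pytest.raises(SeedError):
            pp.holdout_aggregate_ranking(mouse_world.network, disease, sel, [sub])


class TestBenchmarkAndRobustness:
    def test_propagation_beats_random_on_planted_world(self, mouse_world):
        res = pp.benchmark_gene_recovery(mouse_world.human_traits,
                                         mouse_world.mouse_traits,
                                         mouse_world.network, k=5, rng_seed=0)
        means = res["auroc_table"].groupby("strategy")["auroc"].mean()
        assert means["propagation_topk"] > means["random"]

    def test_hold_out_hygiene(self, mouse_world, mouse_profiles):
        # genes held out of the mouse seeds must not sit at guaranteed-top
        # positions purely by being seeds: check no disease seed remains in
        # any used phenotype seed set
        prop, profiles = mouse_profiles
        disease = mouse_world.human_traits[0]
        dp = prop.propagate(disease.seed_genes, trait_id=disease.trait_id)
        sel = pp.select_nearest_phenotypes(dp, profiles, k=10)
        seed_map = {t.trait_id: t.seed_genes for t in mouse_world.mouse_traits}
        for pid in sel.phenotype_ids:
            assert not ((seed_map[pid] - disease.seed_genes) & disease.seed_genes)

    def test_zero_removal_gives_full_stability(self, mouse_world):
        table = pp.selection_robustness(mouse_world.human_traits[:2],
                                        mouse_world.mouse_traits,
                                        mouse_world.network,
                                        removal_fractions=(0.0,),
                                        n_repeats=2, k=5, rng_seed=0)
        assert (table["stability"] == 1.0).all()

    def test_default_removal_fractions(self):
        import inspect
        sig = inspect.signature(pp.selection_robustness)
        assert sig.parameters["removal_fractions"].default == (0.6, 0.8)
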