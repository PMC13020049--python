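import numpy as np
import pytest

import phenoprop as pp
from phenoprop.exceptions import InputError, ModelError


@pytest.fixture(scope="module")
def rich_world():
    """World whose human traits are large enough to train and test on."""
    cfg = pp.SyntheticWorldConfig(n_genes=300, n_modules=10, module_size=25,
                                  n_human_traits=10, n_mouse_traits=20,
                                  human_seeds_range=(20, 25),
                                  multisystemic_frac=0.0, rng_seed=17)
    return pp.generate_world(cfg)


@pytest.fixture(scope="module")
def builder(rich_world):
    return pp.FeatureBuilder(rich_world.network, rich_world.mouse_traits,
                             n_permutations=99)


@pytest.fixture(scope="module")
def model(builder, rich_world):
    return pp.train_combined_model(builder, rich_world.human_traits[:4], rng_seed=0)


class TestFeatureTable:
    def test_features_span_unit_interval(self, builder, rich_world):
        disease = rich_world.human_traits[0]
        table = builder.build(disease.trait_id,
                              sorted(disease.seed_genes)[:5], rng_seed=1)
        for col in table.columns:
            assert table[col].min() == 0.0
            assert table[col].max() == 1.0

    def test_held_out_disease_genes_score_higher(self, builder, rich_world):
        disease = rich_world.human_traits[0]
        seeds = sorted(disease.seed_genes)
        table = builder.build(disease.trait_id, seeds[:5], rng_seed=1)
        held_out = [g for g in seeds[5:] if g in table.index]
        others = [g for g in table.index if g not in disease.seed_genes]
        assert table.loc[held_out, "prop"].mean() > table.loc[others, "prop"].mean()
        assert table.loc[held_out, "mp"].mean() > table.loc[others, "mp"].mean()

    def test_constant_expression_feature_maps_to_zeros(self, rich_world):
        import pandas as pd
        flat = pd.Series(0.5, index=list(rich_world.network.nodes))
        b = pp.FeatureBuilder(rich_world.network, rich_world.mouse_traits,
                              expression_scores=flat, n_permutations=19)
        disease = rich_world.human_traits[0]
        table = b.build(disease.trait_id, sorted(disease.seed_genes)[:5],
                        rng_seed=0, features=("expr",))
        assert (table["expr"] == 0).all()

    def test_determinism(self, builder, rich_world):
        disease = rich_world.human_traits[1]
        t1 = builder.build(disease.trait_id, sorted(disease.seed_genes)[:5],
                           rng_seed=7)
        t2 = builder.build(disease.trait_id, sorted(disease.seed_genes)[:5],
                           rng_seed=7)
        assert t1.equals(t2)


class TestTraining:
    def test_informative_coefficients_are_positive(self, model):
        assert model.coef_["prop"] > 0
        assert model.coef_["mp"] > 0

    def test_negatives_per_round_default(self):
        import inspect
        sig = inspect.signature(pp.train_combined_model)
        assert sig.parameters["negatives_per_round"].default == 150

    def test_round_counts_use_each_gene_once(self, model, rich_world):
        for disease in rich_world.human_traits[:4]:
            n = len(disease.seed_genes)
            assert model.training_info_["rounds"][disease.trait_id] == n // 5

    def test_small_disease_rejected_for_training(self, builder):
        tiny = pp.TraitSeedSet("tiny", "human", frozenset(["G0001", "G0002"]))
        with pytest.raises(ModelError):
            pp.train_combined_model(builder, [tiny])

    def test_empty_feature_subset_rejected(self, builder, rich_world):
        with pytest.raises(InputError):
            pp.GenePrioritizer(features=()).fit(builder, rich_world.human_traits[:4])

    def test_score_monotone_in_positive_features(self, model, builder, rich_world):
        import pandas as pd
        base = pd.DataFrame({"prop": [0.2], "mp": [0.3]}, index=["g"])
        bumped = pd.DataFrame({"prop": [0.4], "mp": [0.3]}, index=["g"])
        assert model.predict_scores(bumped)["g"] >= model.predict_scores(base)["g"]


class TestEvaluation:
    def test_metrics_bounded_and_deterministic(self, model, builder, rich_world):
        test = rich_world.human_traits[4:7]
        m1 = pp.evaluate_model(model, builder, test, n_rounds=2,
                               n_negatives=200, rng_seed=3)
        m2 = pp.evaluate_model(model, builder, test, n_rounds=2,
                               n_negatives=200, rng_seed=3)
        for m in (m1,):
            assert 0 <= m.pr_auc <= 1 and 0 <= m.partial_auroc <= 1 and 0 <= m.auroc <= 1
        assert m1.pr_auc == m2.pr_auc
        assert m1.per_round.equals(m2.per_round)

    def test_combined_model_recovers_disease_genes(self, model, builder, rich_world):
        metrics = pp.evaluate_model(model, builder, rich_world.human_traits[4:8],
                                    n_rounds=2, n_negatives=200, rng_seed=1)
        assert metrics.auroc > 0.8


class TestFinalRanking:
    def test_seed_genes_excluded_and_topk_bounded(self, model, builder, rich_world):
        disease = rich_world.human_traits[0]
        out = pp.final_ranking(model, builder, disease, top_k=50, rng_seed=0)
        assert len(out) == 50
        assert not (set(out.index) & disease.seed_genes)
        assert list(out["rank"]) == list(range(1, 51))

    def test_top_k_default(self):
        import inspect
        sig = inspect.signature(pp.final_ranking)
        assert sig.parameters["top_k"].default == 100

    def test_held_out_genes_enriched_in_top_ranks(self, model, builder, rich_world):
        disease = rich_world.human_traits[5]
        seeds = sorted(disease.seed_genes)
        half = pp.TraitSeedSet(disease.trait_id, "human", frozenset(seeds[:10]))
        out = pp.final_ranking(model, builder, half, top_k=50, rng_seed=0)
        held_out = set(seeds[10:])
        hits = len(set(out.index) & held_out)
        expected_random = 50 / len(out.index.union(held_out)) * 0  # ~ tiny
        frac_in_top = hits / len(held_out)
        background = 50 / (rich_world.network.n_nodes - 10)
        assert frac_in_top > 5 * background
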