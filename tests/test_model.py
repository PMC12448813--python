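"""Model front-end: final embeddings, folds, training, CV and ranking."""

import numpy as np
import pytest

from kglink.contrastive import ContrastiveConfig
from kglink.encoder import LayerEmbeddings
from kglink.graphs import NodeRef
from kglink.model import (
    FoldSplit,
    MicrobeDrugAssociationModel,
    ModelConfig,
    cross_validate,
    final_embedding,
    make_folds,
    rank_candidates,
)
from kglink.transe import TransEConfig

from conftest import random_interactions


def small_config(**kwargs):
    base = dict(
        embed_dim=16, n_layers=3, n_heads=2, layer_budget=8, max_epochs=3,
        batch_size=32, seed=0, transe=TransEConfig(dim=16, epochs=5),
    )
    base.update(kwargs)
    return ModelConfig(**base)


class TestFinalEmbedding:
    def test_length_is_two_lplus1_dim(self):
        L, dim = 3, 64
        rng = np.random.default_rng(0)
        local = LayerEmbeddings(0, "local", rng.standard_normal((L + 1, dim)))
        nonloc = LayerEmbeddings(0, "nonlocal", rng.standard_normal((L + 1, dim)))
        assert final_embedding(local, nonloc).shape == (2 * (L + 1) * dim,)

    def test_zero_layers_zero_vector(self):
        local = LayerEmbeddings(0, "local", np.zeros((4, 8)))
        nonloc = LayerEmbeddings(0, "nonlocal", np.zeros((4, 8)))
        assert (final_embedding(local, nonloc) == 0).all()

    def test_element_order_bookkeeping(self):
        rng = np.random.default_rng(1)
        lv, nv = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        out = final_embedding(LayerEmbeddings(0, "local", lv), LayerEmbeddings(0, "nonlocal", nv))
        expected = np.array(
            [lv[l][k] for l in range(3) for k in range(4)]
            + [nv[l][k] for l in range(3) for k in range(4)]
        )
        assert (out == expected).all()

    def test_shape_mismatch_rejected(self):
        local = LayerEmbeddings(0, "local", np.zeros((4, 8)))
        nonloc = LayerEmbeddings(0, "nonlocal", np.zeros((3, 8)))
        with pytest.raises(ValueError):
            final_embedding(local, nonloc)


class TestMakeFolds:
    def test_even_split_of_ten(self):
        rng = np.random.default_rng(0)
        im = random_interactions(rng, 5, 10, density=0.0)
        vals = im.values.copy()
        pos = [(i, 2 * i) for i in range(5)] + [(i, 2 * i + 1) for i in range(5)]
        for i, j in pos:
            vals[i, j] = 1
        im = type(im)(vals, im.microbe_labels, im.drug_labels)
        folds = make_folds(im, k=5, seed=1)
        assert [len(f.test_positives) for f in folds] == [2] * 5

    def test_partition_balance_and_leakage_invariants(self):
        """Fold partition, balanced negatives and disjointness on 50 random sets."""
        rng = np.random.default_rng(42)
        for trial in range(50):
            im = random_interactions(rng, 10, 14, density=0.25)
            if im.values.sum() < 5:
                continue
            folds = make_folds(im, k=5, seed=trial)
            all_pos = {tuple(p) for p in im.positive_pairs()}
            seen = set()
            for fold in folds:
                test_pos = {tuple(p) for p in fold.test_positives}
                test_neg = {tuple(p) for p in fold.test_negatives}
                train_pos = {tuple(p) for p in fold.train_positives}
                assert len(fold.test_negatives) == len(fold.test_positives)
                assert test_pos.isdisjoint(seen)
                assert test_pos | train_pos == all_pos
                assert test_pos.isdisjoint(train_pos)
                assert test_neg.isdisjoint(all_pos)
                assert test_neg.isdisjoint(train_pos)
                seen |= test_pos
            assert seen == all_pos

    def test_deterministic_given_seed(self, tiny_dataset):
        _, im, _, _ = tiny_dataset
        f1, f2 = make_folds(im, seed=7), make_folds(im, seed=7)
        for a, b in zip(f1, f2):
            assert (a.test_positives == b.test_positives).all()
            assert (a.test_negatives == b.test_negatives).all()

    def test_too_few_positives_rejected(self):
        rng = np.random.default_rng(3)
        im = random_interactions(rng, 4, 4, density=0.0)
        vals = im.values.copy()
        vals[0, 0] = 1
        im = type(im)(vals, im.microbe_labels, im.drug_labels)
        with pytest.raises(ValueError):
            make_folds(im, k=5, seed=0)


class TestTraining:
    def test_single_epoch_history(self, tiny_dataset):
        kg, im, al, _ = tiny_dataset
        model = MicrobeDrugAssociationModel(kg, im, al, small_config(max_epochs=1))
        results = model.fit()
        assert len(results.history) == 1

    def test_zero_weights_equal_ablated_loss_path(self, tiny_dataset):
        """Disabling the contrastive terms via ablation flags or via zero
        weights must give bit-identical pure-BCE training trajectories."""
        kg, im, al, _ = tiny_dataset
        zero_w = ContrastiveConfig(intra_weight=0.0, inter_weight=0.0)
        big_w = ContrastiveConfig(intra_weight=1e9, inter_weight=0.0)
        cfg_a = small_config(max_epochs=2, contrastive=zero_w)
        cfg_b = small_config(max_epochs=2, ablation="no_intra", contrastive=big_w)
        hist_a = MicrobeDrugAssociationModel(kg, im, al, cfg_a).fit().history
        hist_b = MicrobeDrugAssociationModel(kg, im, al, cfg_b).fit().history
        assert [h["train_loss"] for h in hist_a] == [h["train_loss"] for h in hist_b]

    def test_deterministic_given_seed(self, tiny_dataset):
        kg, im, al, _ = tiny_dataset
        cfg = small_config(max_epochs=2, seed=42)
        r1 = MicrobeDrugAssociationModel(kg, im, al, cfg).fit()
        r2 = MicrobeDrugAssociationModel(kg, im, al, cfg).fit()
        assert r1.history == r2.history
        assert (r1.state.final_embeddings == r2.state.final_embeddings).all()

    def test_empty_positives_rejected(self, tiny_dataset):
        kg, im, al, _ = tiny_dataset
        model = MicrobeDrugAssociationModel(kg, im, al, small_config())
        with pytest.raises(ValueError):
            model.fit(train_positives=np.empty((0, 2), dtype=int))

    def test_summary_mentions_dimensions(self, tiny_dataset):
        kg, im, al, _ = tiny_dataset
        results = MicrobeDrugAssociationModel(kg, im, al, small_config(max_epochs=1)).fit()
        text = results.summary()
        assert "microbes: 15" in text and "drugs: 20" in text


class TestCrossValidate:
    def test_report_shape_and_mean(self, tiny_dataset):
        kg, im, al, _ = tiny_dataset
        report = cross_validate(kg, im, al, small_config(max_epochs=2))
        assert len(report.fold_auc) == 5 and len(report.fold_aupr) == 5
        assert report.mean_auc == pytest.approx(np.mean(report.fold_auc))
        assert all(0 <= x <= 1 for x in report.fold_auc + report.fold_aupr)

    def test_cvresults_summary_table(self, tiny_dataset):
        kg, im, al, _ = tiny_dataset
        model = MicrobeDrugAssociationModel(kg, im, al, small_config(max_epochs=2))
        cv = model.cross_validate()
        text = cv.summary()
        assert "mean" in text and text.count("\n") >= 7


@pytest.fixture(scope="module")
def fitted():
    from kglink.synthetic import SyntheticSpec, make_benchmark

    spec = SyntheticSpec(
        n_microbes=15, n_drugs=20, latent_rank=2, interaction_density=0.15,
        n_attribute_entities=30, kg_edges_per_node=4, seed=11,
    )
    kg, im, al, _ = make_benchmark(spec)
    return MicrobeDrugAssociationModel(kg, im, al, small_config(max_epochs=2)).fit()


class TestRankCandidates:
    def test_topk_is_argmax_prefix(self, fitted):
        top1 = fitted.rank_candidates(NodeRef("microbe", 0), k=1)
        top5 = fitted.rank_candidates(NodeRef("microbe", 0), k=5)
        assert top1[0].score == top5[0].score
        assert all(x.score >= y.score for x, y in zip(top5, top5[1:]))

    def test_known_positives_excluded(self, fitted):
        state = fitted.state
        for m in range(state.n_microbes):
            known = set(np.flatnonzero(state.train_matrix[m]).tolist())
            preds = fitted.rank_candidates(NodeRef("microbe", m), k=state.n_drugs)
            assert known.isdisjoint({p.drug for p in preds})

    def test_matches_score_all_then_sort_oracle(self, fitted):
        state = fitted.state
        m = 3
        known = set(np.flatnonzero(state.train_matrix[m]).tolist())
        pairs = np.array([[m, d] for d in range(state.n_drugs)])
        scores = state.pair_scores(pairs)
        candidates = [(d, scores[d]) for d in range(state.n_drugs) if d not in known]
        candidates.sort(key=lambda x: (-x[1], x[0]))
        preds = fitted.rank_candidates(NodeRef("microbe", m), k=4)
        assert [(p.drug, pytest.approx(p.score)) for p in preds] == candidates[:4]

    def test_label_query_and_unknown_label(self, fitted):
        preds = fitted.rank_candidates("m0", k=3)
        assert len(preds) == 3
        with pytest.raises(KeyError):
            fitted.rank_candidates("nonexistent")

    def test_drug_side_query(self, fitted):
        preds = fitted.rank_candidates(NodeRef("drug", 0), k=3)
        assert all(p.drug == 0 for p in preds)
        assert len({p.microbe for p in preds}) == 3


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [dict(ablation="bogus"), dict(n_layers=0), dict(patience=0),
         dict(embed_dim=10, n_heads=4)],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelConfig(**bad)
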