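"""Attention encoder contracts: projections, softmax, pooling, ablation mode."""

import numpy as np
import pytest

from kglink.encoder import (
    EncoderWeights,
    attention_weights,
    build_qkv,
    encode_anchor,
    encode_layer,
    init_encoder_weights,
)
from kglink.graphs import LayeredEntitySets, LayeredTripleSets, NodeRef
from kglink.transe import EmbeddingTable


def random_embeddings(rng, n_ent=12, n_rel=3, dim=8):
    return EmbeddingTable(rng.standard_normal((n_ent, dim)), rng.standard_normal((n_rel, dim)))


def identity_weights(dim):
    """Single head, d_h = dim, identity key/value/output projections."""
    return EncoderWeights(
        w_query=np.vstack([np.eye(dim), np.zeros((dim, dim))])[None],
        w_key=np.eye(dim)[None],
        w_value=np.eye(dim)[None],
        w_output=np.eye(dim),
    )


def loop_encode_layer(triples, emb, weights):
    """Fully-looped reference: per-head scalar attention then output projection."""
    triples = np.asarray(triples).reshape(-1, 3)
    head_outputs = []
    for head in range(weights.n_heads):
        q, k, v = [], [], []
        for h, r, t in triples:
            hr = np.concatenate([emb.entity_vectors[h], emb.relation_vectors[r]])
            q.append(hr @ weights.w_query[head])
            k.append(emb.entity_vectors[t] @ weights.w_key[head])
            v.append(emb.entity_vectors[t] @ weights.w_value[head])
        n = len(triples)
        pooled = np.zeros(weights.head_dim)
        for i in range(n):
            logits = np.array([q[i] @ k[j] / np.sqrt(weights.head_dim) for j in range(n)])
            logits -= logits.max()
            alpha = np.exp(logits) / np.exp(logits).sum()
            out_i = sum(alpha[j] * v[j] for j in range(n))
            pooled += out_i / n
        head_outputs.append(pooled)
    return np.concatenate(head_outputs) @ weights.w_output


class TestBuildQKV:
    def test_identity_key_equals_tail_embedding(self):
        rng = np.random.default_rng(0)
        emb = random_embeddings(rng, dim=4)
        w = identity_weights(4)
        triples = np.array([[0, 0, 3], [1, 1, 2]])
        _, k, v = build_qkv(triples, emb, w, head=0)
        assert np.allclose(k, emb.entity_vectors[[3, 2]])
        assert np.allclose(v, emb.entity_vectors[[3, 2]])

    def test_single_triple_single_tuple(self):
        rng = np.random.default_rng(1)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2, seed=0)
        q, k, v = build_qkv(np.array([[0, 0, 1]]), emb, w, head=1)
        assert q.shape == k.shape == v.shape == (1, 4)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(2)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2, seed=3)
        triples = np.column_stack(
            [rng.integers(12, size=6), rng.integers(3, size=6), rng.integers(12, size=6)]
        )
        q, k, v = build_qkv(triples, emb, w, head=0)
        for i, (h, r, t) in enumerate(triples):
            hr = np.concatenate([emb.entity_vectors[h], emb.relation_vectors[r]])
            assert np.allclose(q[i], hr @ w.w_query[0])
            assert np.allclose(k[i], emb.entity_vectors[t] @ w.w_key[0])

    def test_empty_set_rejected(self):
        rng = np.random.default_rng(3)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2)
        with pytest.raises(ValueError):
            build_qkv(np.empty((0, 3)), emb, w, 0)


class TestAttentionWeights:
    def test_single_key_weight_one(self):
        rng = np.random.default_rng(0)
        q, k = rng.standard_normal((1, 4)), rng.standard_normal((1, 4))
        assert attention_weights(q, k, 4) == pytest.approx(1.0)

    def test_identical_keys_uniform(self):
        rng = np.random.default_rng(1)
        q = rng.standard_normal((3, 4))
        k = np.tile(rng.standard_normal(4), (5, 1))
        alpha = attention_weights(q, k, 4)
        assert np.allclose(alpha, 1 / 5)

    def test_matches_scalar_softmax_oracle(self):
        rng = np.random.default_rng(2)
        q, k = rng.standard_normal((4, 6)), rng.standard_normal((6, 6))
        alpha = attention_weights(q, k, 6)
        for i in range(4):
            logits = [q[i] @ k[j] / np.sqrt(6) for j in range(6)]
            shift = max(logits)
            exps = [np.exp(x - shift) for x in logits]
            assert np.allclose(alpha[i], np.array(exps) / sum(exps))

    @pytest.mark.parametrize("n", [1, 2, 3, 7, 16, 33, 64])
    def test_rows_stochastic(self, n):
        rng = np.random.default_rng(n)
        alpha = attention_weights(rng.standard_normal((n, 8)), rng.standard_normal((n, 8)), 8)
        assert np.abs(alpha.sum(axis=1) - 1).max() < 1e-9
        assert (alpha > 0).all() and (alpha <= 1).all()

    def test_large_offset_stability(self):
        """Adding +1e4 to every logit must not change the weights (max-shift)."""
        rng = np.random.default_rng(5)
        q, k = rng.standard_normal((4, 4)), rng.standard_normal((5, 4))
        # an appended constant column adds the same offset to every logit
        k_ext = np.hstack([k, np.ones((5, 1))])
        offset = attention_weights(np.hstack([q, np.full((4, 1), 1e4)]), k_ext, 4)
        base = attention_weights(np.hstack([q, np.zeros((4, 1))]), k_ext, 4)
        assert np.abs(offset - base).max() < 1e-6


class TestEncodeLayer:
    def test_empty_layer_zero_vector(self):
        rng = np.random.default_rng(0)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2)
        assert (encode_layer(np.empty((0, 3)), emb, w) == 0).all()

    def test_single_triple_identity_projections(self):
        rng = np.random.default_rng(1)
        emb = random_embeddings(rng, dim=4)
        w = identity_weights(4)
        out = encode_layer(np.array([[0, 0, 3]]), emb, w)
        assert np.allclose(out, emb.entity_vectors[3])

    @pytest.mark.parametrize("n", [1, 3, 8, 20])
    def test_matches_loop_oracle(self, n):
        rng = np.random.default_rng(n)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 4, seed=n)
        triples = np.column_stack(
            [rng.integers(12, size=n), rng.integers(3, size=n), rng.integers(12, size=n)]
        )
        assert np.allclose(
            encode_layer(triples, emb, w), loop_encode_layer(triples, emb, w), atol=1e-9
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2, seed=1)
        triples = np.column_stack(
            [rng.integers(12, size=10), rng.integers(3, size=10), rng.integers(12, size=10)]
        )
        base = encode_layer(triples, emb, w)
        shuffled = encode_layer(triples[rng.permutation(10)], emb, w)
        assert np.abs(base - shuffled).max() < 1e-9


class TestEncodeAnchor:
    def build(self, rng, L=3):
        anchor = NodeRef("microbe", 0)
        layers = [
            np.column_stack(
                [rng.integers(12, size=4), rng.integers(3, size=4), rng.integers(12, size=4)]
            )
            for _ in range(L)
        ]
        trips = LayeredTripleSets(anchor, "local", layers)
        ents = LayeredEntitySets(anchor, "local", [{0, 1}] + [set() for _ in range(L)])
        return trips, ents

    def test_layer_count(self):
        rng = np.random.default_rng(0)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2)
        trips, ents = self.build(rng, L=3)
        out = encode_anchor(trips, ents, emb, w)
        assert out.vectors.shape == (4, 8)

    def test_mean_pool_single_triple_is_tail(self):
        rng = np.random.default_rng(1)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2)
        anchor = NodeRef("drug", 1)
        trips = LayeredTripleSets(anchor, "local", [np.array([[0, 0, 5]])])
        ents = LayeredEntitySets(anchor, "local", [{2}, {5}])
        out = encode_anchor(trips, ents, emb, w, mode="mean-pool")
        assert np.allclose(out.vectors[1], emb.entity_vectors[5])

    def test_forced_uniform_attention_equals_mean_pool(self):
        """Zero key projection makes attention uniform; with identity value and
        output projections attention then equals tail mean-pooling."""
        rng = np.random.default_rng(2)
        emb = random_embeddings(rng, dim=4)
        w = identity_weights(4)
        w.w_key[:] = 0.0
        anchor = NodeRef("microbe", 2)
        layer = np.column_stack(
            [rng.integers(12, size=6), rng.integers(3, size=6), rng.integers(12, size=6)]
        )
        trips = LayeredTripleSets(anchor, "nonlocal", [layer])
        ents = LayeredEntitySets(anchor, "nonlocal", [{0}, set(layer[:, 2])])
        att = encode_anchor(trips, ents, emb, w, mode="attention")
        pool = encode_anchor(trips, ents, emb, w, mode="mean-pool")
        assert np.allclose(att.vectors, pool.vectors, atol=1e-12)

    def test_layer0_is_seed_mean_and_empty_is_zero(self):
        rng = np.random.default_rng(3)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2)
        trips, ents = self.build(rng, L=2)
        out = encode_anchor(trips, ents, emb, w)
        assert np.allclose(out.vectors[0], emb.entity_vectors[[0, 1]].mean(axis=0))
        ents_empty = LayeredEntitySets(trips.anchor, "local", [set(), set(), set()])
        out2 = encode_anchor(trips, ents_empty, emb, w)
        assert (out2.vectors[0] == 0).all()

    def test_mismatched_contexts_rejected(self):
        rng = np.random.default_rng(4)
        emb = random_embeddings(rng)
        w = init_encoder_weights(8, 2)
        trips, ents = self.build(rng)
        ents.context = "nonlocal"
        with pytest.raises(ValueError):
            encode_anchor(trips, ents, emb, w)
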