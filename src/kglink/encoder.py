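"""Multi-head attention encoding of per-layer triple sets.

Each layer of an anchor's layered graph is a *set* of triples.  For every
triple ``i`` the concatenated head and relation embeddings form the query
``q_i = proj([e_h ∥ e_r])``, and the tail embedding forms the key and value
``k_i = v_i = proj(e_t)`` (per-head learned projections down to the head
dimension ``d_h``, with ``H · d_h = dim``).  Scaled dot-product attention
over all triples of the layer yields per-query head outputs; the query axis
is mean-pooled per head, the heads are concatenated and an output projection
``W_O`` maps back to the model dimension — one fixed-length vector per
layer.  An empty layer encodes to the zero vector.

Layer 0 has no triples: its vector is the mean of the layer-0 entity set's
embeddings.

``mode="mean-pool"`` replaces attention by the unweighted mean of tail
embeddings (the attention-free ablation).

This module is the plain-numpy reference used by the tests; the training
loop re-implements the same computation batched over anchors on the
autodiff engine, and the two are asserted equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import LayeredEntitySets, LayeredTripleSets
from .transe import EmbeddingTable

__all__ = [
    "EncoderWeights",
    "LayerEmbeddings",
    "init_encoder_weights",
    "build_qkv",
    "attention_weights",
    "encode_layer",
    "encode_anchor",
]


@dataclass
class EncoderWeights:
    """Projection weights of the multi-head layer encoder.

    ``w_query`` is ``(H, 2·dim, d_h)``; ``w_key`` and ``w_value`` are
    ``(H, dim, d_h)``; ``w_output`` is ``(H·d_h, dim)`` with
    ``H · d_h = dim``.
    """

    w_query: np.ndarray
    w_key: np.ndarray
    w_value: np.ndarray
    w_output: np.ndarray

    def __post_init__(self) -> None:
        h, two_dim, d_h = self.w_query.shape
        if self.w_key.shape != (h, two_dim // 2, d_h) or self.w_value.shape != self.w_key.shape:
            raise ValueError("inconsistent projection shapes")
        if h * d_h != two_dim // 2:
            raise ValueError("n_heads * head_dim must equal the model dimension")
        if self.w_output.shape != (h * d_h, two_dim // 2):
            raise ValueError("output projection must be (H*d_h, dim)")

    @property
    def n_heads(self) -> int:
        return self.w_query.shape[0]

    @property
    def head_dim(self) -> int:
        return self.w_query.shape[2]

    @property
    def dim(self) -> int:
        return self.w_key.shape[1]


@dataclass
class LayerEmbeddings:
    """Per-layer vectors ``E^(0) .. E^(L)`` for one anchor and context."""

    anchor: object
    context: str
    vectors: np.ndarray  # (L+1, dim)


def init_encoder_weights(dim: int, n_heads: int = 4, seed: int = 0) -> EncoderWeights:
    """Seeded near-orthogonal uniform initialisation (scaled Glorot-style)."""
    if dim % n_heads != 0:
        raise ValueError("dim must be divisible by n_heads")
    d_h = dim // n_heads
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))

    def init(*shape):
        bound = np.sqrt(6.0 / (shape[-2] + shape[-1]))
        return rng.uniform(-bound, bound, size=shape)

    return EncoderWeights(
        w_query=init(n_heads, 2 * dim, d_h),
        w_key=init(n_heads, dim, d_h),
        w_value=init(n_heads, dim, d_h),
        w_output=init(dim, dim),
    )


def build_qkv(
    triples: np.ndarray, emb: EmbeddingTable, weights: EncoderWeights, head: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-triple query/key/value rows for one attention head."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    if len(triples) == 0:
        raise ValueError("build_qkv requires a non-empty triple set")
    h_emb = emb.entity_vectors[triples[:, 0]]
    r_emb = emb.relation_vectors[triples[:, 1]]
    t_emb = emb.entity_vectors[triples[:, 2]]
    q = np.concatenate([h_emb, r_emb], axis=1) @ weights.w_query[head]
    k = t_emb @ weights.w_key[head]
    v = t_emb @ weights.w_value[head]
    return q, k, v


def attention_weights(queries: np.ndarray, keys: np.ndarray, d_h: int) -> np.ndarray:
    """Row-stochastic scaled dot-product attention matrix (max-shifted)."""
    logits = queries @ keys.T / np.sqrt(d_h)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def encode_layer(
    triples: np.ndarray, emb: EmbeddingTable, weights: EncoderWeights
) -> np.ndarray:
    """Encode one layer's triple set into a ``dim`` vector (zero if empty)."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    if len(triples) == 0:
        return np.zeros(weights.dim, dtype=emb.entity_vectors.dtype)
    head_outputs = []
    for head in range(weights.n_heads):
        q, k, v = build_qkv(triples, emb, weights, head)
        alpha = attention_weights(q, k, weights.head_dim)
        per_query = alpha @ v  # (n, d_h)
        head_outputs.append(per_query.mean(axis=0))
    return np.concatenate(head_outputs) @ weights.w_output


def _mean_pool_layer(
    triples: np.ndarray, emb: EmbeddingTable, dim: int
) -> np.ndarray:
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    if len(triples) == 0:
        return np.zeros(dim, dtype=emb.entity_vectors.dtype)
    return emb.entity_vectors[triples[:, 2]].mean(axis=0)


def encode_anchor(
    layered: LayeredTripleSets,
    seeds: LayeredEntitySets,
    emb: EmbeddingTable,
    weights: EncoderWeights,
    mode: str = "attention",
) -> LayerEmbeddings:
    """Encode all layers of one anchor/context into an ``(L+1, dim)`` stack.

    Vector 0 is the mean embedding of the layer-0 entity set (zero if
    empty); vectors ``1..L`` encode the triple sets, by attention or by
    unweighted tail mean-pooling (the attention-free variant).
    """
    if layered.context != seeds.context or layered.anchor != seeds.anchor:
        raise ValueError("triple sets and entity sets refer to different anchors/contexts")
    if mode not in ("attention", "mean-pool"):
        raise ValueError(f"unknown encoder mode {mode!r}")
    dim = weights.dim
    seed_set = sorted(seeds.layers[0])
    rows = [
        emb.entity_vectors[seed_set].mean(axis=0)
        if seed_set
        else np.zeros(dim, dtype=emb.entity_vectors.dtype)
    ]
    for layer_triples in layered.layers:
        if mode == "attention":
            rows.append(encode_layer(layer_triples, emb, weights))
        else:
            rows.append(_mean_pool_layer(layer_triples, emb, dim))
    return LayerEmbeddings(layered.anchor, layered.context, np.vstack(rows))
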