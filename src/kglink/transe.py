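"""Translational KG embedding pretraining (margin-based ranking loss).

The translational model scores a triple ``(h, r, t)`` by
``f(h, r, t) = || e_h + e_r − e_t ||`` (L1 or L2); low scores mean
plausible triples.  Training minimises the hinge

    sum over triples of  max(0, γ + f(pos) − f(neg))

with one (or more) corrupted triples per positive, obtained by replacing the
head or the tail (fair coin) with a uniformly drawn different entity.
Entity vectors are renormalised to unit norm at the start of each epoch,
the canonical regularisation for this model family.  The resulting table
*initialises* the trainable embeddings of the full predictor; it is not
frozen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import KnowledgeGraph, Triple

__all__ = ["TransEConfig", "EmbeddingTable", "score", "corrupt", "margin_loss", "pretrain",
           "save_embeddings", "load_embeddings"]


@dataclass
class TransEConfig:
    dim: int = 64
    margin: float = 1.0
    norm_order: int = 2
    learning_rate: float = 0.01
    epochs: int = 100
    negatives_per_positive: int = 1
    batch_size: int = 128
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.norm_order not in (1, 2):
            raise ValueError("norm_order must be 1 or 2")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")


@dataclass
class EmbeddingTable:
    """Entity and relation vectors (rows aligned with KG indices)."""

    entity_vectors: np.ndarray
    relation_vectors: np.ndarray

    @property
    def dim(self) -> int:
        return self.entity_vectors.shape[1]

    def copy(self) -> "EmbeddingTable":
        return EmbeddingTable(self.entity_vectors.copy(), self.relation_vectors.copy())


def score(triple: Triple | tuple[int, int, int], emb: EmbeddingTable, norm_order: int = 2) -> float:
    """Plausibility score ``||e_h + e_r − e_t||``; lower is more plausible."""
    h, r, t = triple
    diff = emb.entity_vectors[h] + emb.relation_vectors[r] - emb.entity_vectors[t]
    return float(np.linalg.norm(diff, ord=norm_order))


def _batch_scores(triples: np.ndarray, emb: EmbeddingTable, norm_order: int) -> np.ndarray:
    diff = (
        emb.entity_vectors[triples[:, 0]]
        + emb.relation_vectors[triples[:, 1]]
        - emb.entity_vectors[triples[:, 2]]
    )
    if norm_order == 1:
        return np.abs(diff).sum(axis=1)
    return np.sqrt((diff * diff).sum(axis=1))


def corrupt(
    triple: Triple | tuple[int, int, int], entity_count: int, rng: np.random.Generator
) -> Triple:
    """Corrupt head or tail (fair coin) with a uniform *different* entity."""
    if entity_count < 2:
        raise ValueError("need at least 2 entities to corrupt a triple")
    h, r, t = triple
    corrupt_head = rng.random() < 0.5
    original = h if corrupt_head else t
    repl = int(rng.integers(0, entity_count - 1))
    if repl >= original:
        repl += 1
    return Triple(repl, r, t) if corrupt_head else Triple(h, r, repl)


def _corrupt_batch(
    triples: np.ndarray, entity_count: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised corruption of a batch, same scheme as :func:`corrupt`."""
    out = triples.copy()
    corrupt_head = rng.random(len(triples)) < 0.5
    repl = rng.integers(0, entity_count - 1, size=len(triples))
    original = np.where(corrupt_head, triples[:, 0], triples[:, 2])
    repl = np.where(repl >= original, repl + 1, repl)
    out[corrupt_head, 0] = repl[corrupt_head]
    out[~corrupt_head, 2] = repl[~corrupt_head]
    return out


def margin_loss(
    pos: np.ndarray, neg: np.ndarray, emb: EmbeddingTable, config: TransEConfig
) -> float:
    """Hinge loss ``Σ max(0, γ + f(pos) − f(neg))`` over aligned batches."""
    pos = np.asarray(pos, dtype=np.int64).reshape(-1, 3)
    neg = np.asarray(neg, dtype=np.int64).reshape(-1, 3)
    if len(pos) != len(neg):
        raise ValueError("positive and negative batches must align one-to-one")
    f_pos = _batch_scores(pos, emb, config.norm_order)
    f_neg = _batch_scores(neg, emb, config.norm_order)
    return float(np.maximum(0.0, config.margin + f_pos - f_neg).sum())


def _init_table(kg: KnowledgeGraph, config: TransEConfig) -> EmbeddingTable:
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(10,)))
    bound = 6.0 / np.sqrt(config.dim)
    ent = rng.uniform(-bound, bound, size=(kg.entity_count, config.dim))
    rel = rng.uniform(-bound, bound, size=(kg.relation_count, config.dim))
    rel /= np.maximum(np.linalg.norm(rel, axis=1, keepdims=True), 1e-12)
    return EmbeddingTable(ent, rel)


def pretrain(
    kg: KnowledgeGraph, config: TransEConfig | None = None, return_history: bool = False
):
    """Pretrain embeddings on the KG by mini-batch SGD on the hinge loss.

    Deterministic given ``config.seed``.  With ``epochs=0`` the seeded
    initialisation is returned unchanged.  Entity vectors are renormalised
    to unit norm at the start of every epoch.
    """
    config = config or TransEConfig()
    if kg.n_triples == 0:
        raise ValueError("cannot pretrain on a knowledge graph with zero triples")
    emb = _init_table(kg, config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(11,)))
    triples = kg.triples
    n = len(triples)
    history: list[float] = []
    if return_history:
        # deterministic learning curve: hinge loss on a fixed corruption set,
        # measured after each epoch
        eval_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(12,)))
        eval_pos = np.repeat(triples, 5, axis=0)
        eval_neg = _corrupt_batch(eval_pos, kg.entity_count, eval_rng)
    for _ in range(config.epochs):
        emb.entity_vectors /= np.maximum(
            np.linalg.norm(emb.entity_vectors, axis=1, keepdims=True), 1e-12
        )
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = triples[order[start : start + config.batch_size]]
            reps = config.negatives_per_positive
            pos = np.repeat(batch, reps, axis=0) if reps > 1 else batch
            neg = _corrupt_batch(pos, kg.entity_count, rng)
            _sgd_step(pos, neg, emb, config)
        if return_history:
            history.append(margin_loss(eval_pos, eval_neg, emb, config) / len(eval_pos))
    if return_history:
        return emb, history
    return emb


def _sgd_step(
    pos: np.ndarray, neg: np.ndarray, emb: EmbeddingTable, config: TransEConfig
) -> float:
    """One hinge-loss SGD step over aligned pos/neg batches; returns loss."""
    ent, rel = emb.entity_vectors, emb.relation_vectors

    def diff_and_score(tr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = ent[tr[:, 0]] + rel[tr[:, 1]] - ent[tr[:, 2]]
        if config.norm_order == 1:
            return d, np.abs(d).sum(axis=1)
        return d, np.sqrt((d * d).sum(axis=1))

    d_pos, f_pos = diff_and_score(pos)
    d_neg, f_neg = diff_and_score(neg)
    slack = config.margin + f_pos - f_neg
    active = slack > 0
    loss = float(slack[active].sum())
    if not active.any():
        return loss

    def norm_grad(d: np.ndarray, f: np.ndarray) -> np.ndarray:
        if config.norm_order == 1:
            return np.sign(d)
        return d / np.maximum(f, 1e-12)[:, None]

    g_pos = norm_grad(d_pos[active], f_pos[active])  # dL/d(diff_pos)
    g_neg = -norm_grad(d_neg[active], f_neg[active])  # dL/d(diff_neg)
    lr = config.learning_rate
    grad_ent = np.zeros_like(ent)
    grad_rel = np.zeros_like(rel)
    pa, na = pos[active], neg[active]
    np.add.at(grad_ent, pa[:, 0], g_pos)
    np.add.at(grad_ent, pa[:, 2], -g_pos)
    np.add.at(grad_rel, pa[:, 1], g_pos)
    np.add.at(grad_ent, na[:, 0], g_neg)
    np.add.at(grad_ent, na[:, 2], -g_neg)
    np.add.at(grad_rel, na[:, 1], g_neg)
    ent -= lr * grad_ent
    rel -= lr * grad_rel
    return loss


def save_embeddings(
    emb: EmbeddingTable, kg: KnowledgeGraph, entities_path, relations_path
) -> None:
    """Write entity / relation tables as label-first TSVs."""
    for path, labels, mat in (
        (entities_path, kg.entity_labels, emb.entity_vectors),
        (relations_path, kg.relation_labels, emb.relation_vectors),
    ):
        with open(path, "w", encoding="utf-8") as fh:
            for lab, row in zip(labels, mat):
                fh.write(lab + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")


def load_embeddings(entities_path, relations_path, kg: KnowledgeGraph) -> EmbeddingTable:
    """Read tables written by :func:`save_embeddings`, reordered to KG indices."""

    def read(path, labels):
        rows: dict[str, np.ndarray] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows[parts[0]] = np.array([float(x) for x in parts[1:]])
        return np.vstack([rows[lab] for lab in labels])

    return EmbeddingTable(
        read(entities_path, kg.entity_labels), read(relations_path, kg.relation_labels)
    )
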