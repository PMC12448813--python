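"""Batched trainable forward pass and the joint training loop.

The public modules (:mod:`kglink.encoder`, :mod:`kglink.contrastive`,
:mod:`kglink.metrics`) define the per-anchor reference computation; this
module re-implements the identical mathematics batched over anchors on the
autodiff engine so one optimisation step touches every anchor of a
mini-batch at once.  The test-suite asserts the two routes agree.

Anchor indexing: microbe ``i`` is anchor ``i``; drug ``j`` is anchor
``n_microbes + j``.  Per anchor there are two contexts (0 = local,
1 = non-local), each with ``L + 1`` layer vectors; the final node
representation is the flattened ``(2, L+1, dim)`` stack and a pair's score
is the sigmoid of the dot product of the two representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Adam, Parameter, Tensor, sparse_matmul
from .data import EntityAlignment, InteractionMatrix, KnowledgeGraph
from .encoder import EncoderWeights, init_encoder_weights
from .graphs import build_all_graphs
from .metrics import compute_roc_auc
from .transe import EmbeddingTable, TransEConfig, pretrain

__all__ = ["PackedGraphs", "pack_graphs", "AssociationNetwork", "fit_network"]

_CTX = ("local", "nonlocal")


@dataclass
class PackedGraphs:
    """Padded arrays of all anchors' layered structures.

    Segment ``(anchor a, context c, layer l ∈ 1..L)`` lives at row
    ``(a * 2 + c) * L + (l - 1)`` of the triple arrays; the seed (layer-0)
    entity sets live at row ``a * 2 + c`` of the seed arrays.
    """

    n_anchors: int
    n_layers: int
    seed_mean: object  # CSR (A*2, entity_count), rows normalised to mean weights
    trip_h: np.ndarray  # (A*2*L, T_max) int64
    trip_r: np.ndarray
    trip_t: np.ndarray
    trip_mask: np.ndarray  # (A*2*L, T_max) bool


def pack_graphs(
    graphs: dict, n_microbes: int, n_drugs: int, n_layers: int, entity_count: int
) -> PackedGraphs:
    """Pad the per-anchor layered structures into dense index arrays."""
    from scipy import sparse

    A = n_microbes + n_drugs
    seed_sets: list[list[int]] = []
    layer_trips: list[np.ndarray] = []
    for a in range(A):
        side, idx = ("microbe", a) if a < n_microbes else ("drug", a - n_microbes)
        for ctx in _CTX:
            trips, ents = graphs[(side, idx, ctx)]
            seed_sets.append(sorted(ents.layers[0]))
            for l in range(n_layers):
                layer_trips.append(np.asarray(trips.layers[l], dtype=np.int64).reshape(-1, 3))
    t_max = max(1, max(len(t) for t in layer_trips))
    indptr = np.cumsum([0] + [len(s) for s in seed_sets])
    indices = np.concatenate([np.asarray(s, dtype=np.int64) for s in seed_sets] or [[]])
    weights = np.concatenate(
        [np.full(len(s), 1.0 / len(s)) if s else np.zeros(0) for s in seed_sets] or [[]]
    )
    seed_mean = sparse.csr_matrix(
        (weights, indices, indptr), shape=(A * 2, entity_count)
    )
    n_seg = A * 2 * n_layers
    trip_h = np.zeros((n_seg, t_max), dtype=np.int64)
    trip_r = np.zeros((n_seg, t_max), dtype=np.int64)
    trip_t = np.zeros((n_seg, t_max), dtype=np.int64)
    trip_mask = np.zeros((n_seg, t_max), dtype=bool)
    for i, tr in enumerate(layer_trips):
        n = len(tr)
        if n:
            trip_h[i, :n] = tr[:, 0]
            trip_r[i, :n] = tr[:, 1]
            trip_t[i, :n] = tr[:, 2]
            trip_mask[i, :n] = True
    return PackedGraphs(A, n_layers, seed_mean, trip_h, trip_r, trip_t, trip_mask)


class AssociationNetwork:
    """Trainable parameters + batched forward of the association model."""

    def __init__(
        self,
        entity_count: int,
        relation_count: int,
        packed: PackedGraphs,
        dim: int,
        n_heads: int,
        init_embeddings: EmbeddingTable | None = None,
        encoder_seed: int = 0,
        attention: bool = True,
        dtype=np.float32,
    ):
        self.packed = packed
        self._seed_mean = packed.seed_mean.astype(dtype)
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.attention = attention
        self.dtype = dtype
        if init_embeddings is not None:
            ent = init_embeddings.entity_vectors
            rel = init_embeddings.relation_vectors
        else:
            rng = np.random.default_rng(np.random.SeedSequence(encoder_seed, spawn_key=(21,)))
            bound = 6.0 / np.sqrt(dim)
            ent = rng.uniform(-bound, bound, (entity_count, dim))
            rel = rng.uniform(-bound, bound, (relation_count, dim))
        self.entity_emb = Parameter(ent.astype(dtype))
        self.relation_emb = Parameter(rel.astype(dtype))
        ew = init_encoder_weights(dim, n_heads, seed=encoder_seed)
        # combined per-head projections: (2d, H*d_h) etc., head-major blocks
        self.w_query = Parameter(
            np.concatenate([ew.w_query[h] for h in range(n_heads)], axis=1).astype(dtype)
        )
        self.w_key = Parameter(
            np.concatenate([ew.w_key[h] for h in range(n_heads)], axis=1).astype(dtype)
        )
        self.w_value = Parameter(
            np.concatenate([ew.w_value[h] for h in range(n_heads)], axis=1).astype(dtype)
        )
        self.w_output = Parameter(ew.w_output.astype(dtype))

    @property
    def parameters(self) -> list[Parameter]:
        params = [self.entity_emb, self.relation_emb]
        if self.attention:
            params += [self.w_query, self.w_key, self.w_value, self.w_output]
        return params

    def encoder_weights(self) -> EncoderWeights:
        """Current encoder weights in the per-head layout of :mod:`kglink.encoder`."""
        H, dh = self.n_heads, self.head_dim
        split = lambda w: np.stack([w[:, h * dh : (h + 1) * dh] for h in range(H)])
        return EncoderWeights(
            split(self.w_query.value.astype(np.float64)),
            split(self.w_key.value.astype(np.float64)),
            split(self.w_value.value.astype(np.float64)),
            self.w_output.value.astype(np.float64),
        )

    def embedding_table(self) -> EmbeddingTable:
        return EmbeddingTable(
            self.entity_emb.value.astype(np.float64),
            self.relation_emb.value.astype(np.float64),
        )

    # -- forward ------------------------------------------------------------

    def layer_tensor(self, anchors: np.ndarray) -> Tensor:
        """Layer embeddings for the given anchors: (n, 2, L+1, dim)."""
        p = self.packed
        L, d, H, dh = p.n_layers, self.dim, self.n_heads, self.head_dim
        anchors = np.asarray(anchors, dtype=np.int64)
        n = len(anchors)
        rows = (anchors[:, None] * 2 + np.arange(2)[None, :]).reshape(-1)  # (n*2,)
        segs = (rows[:, None] * L + np.arange(L)[None, :]).reshape(-1)  # (n*2*L,)

        # layer 0: mean of seed-entity embeddings (row-normalised sparse matmul)
        layer0 = sparse_matmul(self._seed_mean[rows], self.entity_emb)  # (n2, d)

        # layers 1..L
        tmask = p.trip_mask[segs]  # (S_seg, T)
        t_emb = self.entity_emb.gather(p.trip_t[segs])  # (S_seg, T, d)
        fmask = tmask.astype(self.dtype)
        if not self.attention:
            cnt = np.maximum(fmask.sum(axis=1, keepdims=True), 1.0)
            enc = (t_emb * fmask[:, :, None]).sum(axis=1) * (1.0 / cnt)  # (S_seg, d)
        else:
            h_emb = self.entity_emb.gather(p.trip_h[segs])
            r_emb = self.relation_emb.gather(p.trip_r[segs])
            q_in = Tensor.concat([h_emb, r_emb], axis=-1)  # (S_seg, T, 2d)
            S_seg, T = tmask.shape

            def heads(x: Tensor) -> Tensor:
                # (S_seg, T, H*dh) -> (S_seg, H, T, dh)
                return x.reshape(S_seg, T, H, dh).swapaxes(1, 2)

            Q = heads(q_in @ self.w_query)
            K = heads(t_emb @ self.w_key)
            V = heads(t_emb @ self.w_value)
            logits = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (S_seg, H, T, T)
            alpha = logits.masked_softmax(tmask[:, None, None, :], axis=-1)
            per_query = alpha @ V  # (S_seg, H, T, dh)
            qmask = fmask[:, None, :, None]
            cnt = np.maximum(fmask.sum(axis=1), 1.0)[:, None, None]  # (S_seg,1,1)
            pooled = (per_query * qmask).sum(axis=2) * (1.0 / cnt)  # (S_seg, H, dh)
            enc = pooled.reshape(S_seg, H * dh) @ self.w_output  # (S_seg, d)

        stack0 = layer0.reshape(n, 2, 1, d)
        stackL = enc.reshape(n, 2, L, d)
        return Tensor.concat([stack0, stackL], axis=2)  # (n, 2, L+1, d)

    def final_from_layers(self, layers: Tensor) -> Tensor:
        n = layers.value.shape[0]
        return layers.reshape(n, 2 * (self.packed.n_layers + 1) * self.dim)

    def pair_logits(self, final: Tensor, pos_m: np.ndarray, pos_d: np.ndarray) -> Tensor:
        """Dot-product logits for pairs given row positions into ``final``."""
        em = final.gather(pos_m)
        ed = final.gather(pos_d)
        return (em * ed).sum(axis=1)

    # -- losses -------------------------------------------------------------

    def bce_from_logits(self, logits: Tensor, labels: np.ndarray) -> Tensor:
        """Mean binary cross-entropy on σ(logit) targets, computed stably."""
        y = labels.astype(self.dtype)
        return (logits.softplus() - logits * y).mean()

    def intra_term(
        self, layers: Tensor, temperature: float, negatives_per_anchor: int,
        rng: np.random.Generator,
    ) -> Tensor:
        """Intra-graph InfoNCE summed over the given anchors and contexts."""
        n, _, Lp1, d = layers.value.shape
        if Lp1 < 3:
            return Tensor(np.zeros((), dtype=self.dtype), requires_grad=False)
        anchor = layers.index((slice(None), slice(None), 0))  # (n,2,d)
        positive = layers.index((slice(None), slice(None), 1))
        cand = Lp1 - 2
        m = min(negatives_per_anchor, cand)
        if m == cand:
            neg_idx = np.broadcast_to(np.arange(2, Lp1), (n, 2, cand)).copy()
        else:
            keys = rng.random((n, 2, cand))
            neg_idx = 2 + np.argsort(keys, axis=-1, kind="stable")[..., :m]
        ii = np.arange(n)[:, None, None]
        cc = np.arange(2)[None, :, None]
        negs = layers.index((ii, cc, neg_idx))  # (n,2,m,d)
        inv_t = 1.0 / temperature
        pos_logit = (anchor * positive).sum(axis=-1) * inv_t  # (n,2)
        neg_logit = (negs * anchor.reshape(n, 2, 1, d)).sum(axis=-1) * inv_t  # (n,2,m)
        all_logits = Tensor.concat([pos_logit.reshape(n, 2, 1), neg_logit], axis=2)
        lse = all_logits.masked_logsumexp(np.ones(all_logits.value.shape, dtype=bool), axis=2)
        return (lse - pos_logit).sum()

    def inter_term(self, layers: Tensor, temperature: float) -> Tensor:
        """Inter-graph InfoNCE summed over the given anchors and layers."""
        n, _, Lp1, d = layers.value.shape
        local = layers.index((slice(None), 0))  # (n, L+1, d)
        nonloc = layers.index((slice(None), 1))
        sims = (local @ nonloc.swapaxes(-1, -2)) * (1.0 / temperature)  # (n, L+1, L+1)
        lse = sims.masked_logsumexp(np.ones(sims.value.shape, dtype=bool), axis=-1)  # (n, L+1)
        diag = sims.index((slice(None), np.arange(Lp1), np.arange(Lp1)))  # (n, L+1)
        return (lse - diag).sum()


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainedState:
    """Best-epoch model state plus everything needed to score pairs."""

    network: AssociationNetwork
    final_embeddings: np.ndarray  # (n_microbes + n_drugs, 2*(L+1)*dim)
    n_microbes: int
    n_drugs: int
    train_matrix: np.ndarray  # the interaction matrix seen during training
    microbe_labels: list[str]
    drug_labels: list[str]
    best_epoch: int
    history: list[dict] = field(default_factory=list)

    def pair_scores(self, pairs: np.ndarray) -> np.ndarray:
        """σ(e_m · e_d) for (microbe, drug) index pairs."""
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        em = self.final_embeddings[pairs[:, 0]]
        ed = self.final_embeddings[self.n_microbes + pairs[:, 1]]
        z = np.clip((em * ed).sum(axis=1), -30, 30)
        return 1.0 / (1.0 + np.exp(-z))


def _sample_negative_pairs(
    n_microbes: int, n_drugs: int, forbidden: set[int], count: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform unknown (microbe, drug) pairs, rejecting ``forbidden`` flat ids."""
    total = n_microbes * n_drugs
    if total - len(forbidden) < count:
        raise ValueError("not enough unknown pairs to sample negatives")
    chosen: list[int] = []
    taken = set(forbidden)
    while len(chosen) < count:
        draw = rng.integers(0, total, size=max(2 * (count - len(chosen)), 16))
        for f in draw:
            f = int(f)
            if f not in taken:
                taken.add(f)
                chosen.append(f)
                if len(chosen) == count:
                    break
    flat = np.array(chosen, dtype=np.int64)
    return np.column_stack([flat // n_drugs, flat % n_drugs])


def _anchor_positions(pairs: np.ndarray, n_microbes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique anchors of a pair batch and each pair's row positions."""
    m_anchor = pairs[:, 0]
    d_anchor = n_microbes + pairs[:, 1]
    anchors, inverse = np.unique(np.concatenate([m_anchor, d_anchor]), return_inverse=True)
    n = len(pairs)
    return anchors, inverse[:n], inverse[n:]


def fit_network(
    kg: KnowledgeGraph,
    im: InteractionMatrix,
    alignment: EntityAlignment,
    config,
    train_positives: np.ndarray | None = None,
    pretrained: EmbeddingTable | None = None,
) -> TrainedState:
    """Train the association network and return the best-epoch state.

    ``train_positives`` defaults to every positive of ``im``.  A fraction
    of them (``config.validation_fraction``) is held out with matched
    negatives for early stopping on validation AUC; both graph construction
    and the supervised loss see only the remaining training positives.
    Deterministic given ``config.seed``.
    """
    n_m, n_d = im.n_microbes, im.n_drugs
    if train_positives is None:
        train_positives = im.positive_pairs()
    train_positives = np.asarray(train_positives, dtype=np.int64).reshape(-1, 2)
    if len(train_positives) == 0:
        raise ValueError("no training positives")

    rng_split, rng_neg, rng_batch, rng_ssl = (
        np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(30, i)))
        for i in range(4)
    )

    # --- validation split ---------------------------------------------------
    n_train = len(train_positives)
    n_val = int(round(config.validation_fraction * n_train))
    order = rng_split.permutation(n_train)
    val_pos = train_positives[order[:n_val]]
    fit_pos = train_positives[order[n_val:]]
    if len(fit_pos) == 0:
        fit_pos, val_pos = train_positives, train_positives[:0]

    known_flat = set((im.positive_pairs()[:, 0] * n_d + im.positive_pairs()[:, 1]).tolist())
    if n_val:
        val_neg = _sample_negative_pairs(n_m, n_d, known_flat, n_val, rng_split)
        val_pairs = np.vstack([val_pos, val_neg])
        val_labels = np.concatenate([np.ones(n_val), np.zeros(n_val)])
    else:
        val_pairs = train_positives[:0]
        val_labels = np.zeros(0)

    # --- graph construction on the fit matrix --------------------------------
    fit_matrix = np.zeros_like(im.values)
    fit_matrix[fit_pos[:, 0], fit_pos[:, 1]] = 1
    fit_im = InteractionMatrix(fit_matrix, im.microbe_labels, im.drug_labels)
    graphs = build_all_graphs(
        kg, fit_im, alignment, config.n_layers, config.layer_budget, seed=config.seed
    )
    packed = pack_graphs(graphs, n_m, n_d, config.n_layers, kg.entity_count)

    # --- network ------------------------------------------------------------
    if pretrained is None:
        tconf = config.transe
        if tconf.dim != config.embed_dim:
            raise ValueError("TransE dim must equal the model embedding dim")
        pretrained = pretrain(kg, tconf)
    net = AssociationNetwork(
        kg.entity_count,
        kg.relation_count,
        packed,
        dim=config.embed_dim,
        n_heads=config.n_heads,
        init_embeddings=pretrained,
        encoder_seed=config.seed,
        attention=(config.ablation != "no_att"),
    )
    opt = Adam(net.parameters, lr=config.learning_rate)
    ssl = config.contrastive
    use_intra = config.ablation not in ("no_intra",) and ssl.intra_weight > 0
    use_inter = config.ablation not in ("no_inter",) and ssl.inter_weight > 0

    fit_flat = set((fit_pos[:, 0] * n_d + fit_pos[:, 1]).tolist())
    best_auc, best_epoch, best_params, since_best = -np.inf, -1, None, 0
    history: list[dict] = []

    for epoch in range(config.max_epochs):
        perm = rng_batch.permutation(len(fit_pos))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(fit_pos), config.batch_size):
            pos_batch = fit_pos[perm[start : start + config.batch_size]]
            neg_batch = _sample_negative_pairs(n_m, n_d, fit_flat, len(pos_batch), rng_neg)
            pairs = np.vstack([pos_batch, neg_batch])
            labels = np.concatenate([np.ones(len(pos_batch)), np.zeros(len(neg_batch))])
            anchors, pm, pd = _anchor_positions(pairs, n_m)
            layers = net.layer_tensor(anchors)
            final = net.final_from_layers(layers)
            loss = net.bce_from_logits(net.pair_logits(final, pm, pd), labels)
            if use_intra:
                loss = loss + net.intra_term(
                    layers, ssl.temperature, ssl.negatives_per_anchor, rng_ssl
                ) * ssl.intra_weight
            if use_inter:
                loss = loss + net.inter_term(layers, ssl.temperature) * ssl.inter_weight
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.value)
            n_batches += 1
        record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
        if len(val_pairs):
            scores = _score_pairs(net, val_pairs, n_m)
            try:
                val_auc = compute_roc_auc(scores, val_labels)
            except ValueError:
                val_auc = 0.5
            record["val_auc"] = val_auc
            history.append(record)
            if val_auc > best_auc:
                best_auc, best_epoch, since_best = val_auc, epoch, 0
                best_params = [p.value.copy() for p in net.parameters]
            else:
                since_best += 1
                if since_best >= config.patience:
                    break
        else:
            history.append(record)
            best_epoch = epoch
    if best_params is not None:
        for p, v in zip(net.parameters, best_params):
            p.value = v

    final_all = _final_embeddings(net)
    return TrainedState(
        network=net,
        final_embeddings=final_all,
        n_microbes=n_m,
        n_drugs=n_d,
        train_matrix=fit_matrix,
        microbe_labels=list(im.microbe_labels),
        drug_labels=list(im.drug_labels),
        best_epoch=best_epoch,
        history=history,
    )


def _final_embeddings(net: AssociationNetwork, chunk: int = 512) -> np.ndarray:
    A = net.packed.n_anchors
    out = []
    for start in range(0, A, chunk):
        anchors = np.arange(start, min(start + chunk, A))
        layers = net.layer_tensor(anchors)
        out.append(net.final_from_layers(layers).value.astype(np.float64))
    return np.vstack(out)


def _score_pairs(net: AssociationNetwork, pairs: np.ndarray, n_microbes: int) -> np.ndarray:
    anchors, pm, pd = _anchor_positions(pairs, n_microbes)
    final = net.final_from_layers(net.layer_tensor(anchors))
    z = np.clip(net.pair_logits(final, pm, pd).value, -30, 30)
    return 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
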