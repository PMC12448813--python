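"""Intra- and inter-graph InfoNCE contrastive losses over layer embeddings.

Both losses contrast layer vectors of the *same* anchor node:

* **intra-graph** — within each context (local or non-local), the layer-0
  vector is the anchor representation, the adjacent layer (layer 1) is the
  positive, and randomly chosen non-adjacent layers (l ≥ 2) are the
  negatives;
* **inter-graph** — for every layer k, the local layer-k vector is the
  anchor, the non-local layer-k vector is the positive, and the remaining
  non-local layers are the negatives.

Similarity is the raw dot product scaled by a temperature τ (cosine is
available behind a flag).  Totals sum over the microbe side and the drug
side.  The two losses enter the training objective weighted by
``intra_weight`` and ``inter_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .encoder import LayerEmbeddings

__all__ = ["ContrastiveConfig", "infonce", "intra_loss", "inter_loss", "combined_ssl"]


@dataclass
class ContrastiveConfig:
    """Contrastive-learning hyperparameters.

    ``temperature`` is the softmax temperature τ (default 0.1); the weights
    are the coefficients of the intra/inter terms in the joint objective
    (defaults 1e-5 / 1e-5).  ``negatives_per_anchor`` bounds how many
    non-adjacent layers the intra loss samples as negatives.
    """

    temperature: float = 0.1
    intra_weight: float = 1e-5
    inter_weight: float = 1e-5
    negatives_per_anchor: int = 1
    cosine: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.intra_weight < 0 or self.inter_weight < 0:
            raise ValueError("contrastive weights must be non-negative")


def _sim(a: np.ndarray, b: np.ndarray, cosine: bool) -> np.ndarray:
    if cosine:
        a = a / max(np.linalg.norm(a), 1e-12)
        b = b / np.maximum(np.linalg.norm(b, axis=-1, keepdims=True), 1e-12)
    return b @ a


def infonce(
    anchor: np.ndarray,
    positive: np.ndarray,
    negatives: Sequence[np.ndarray],
    temperature: float,
    cosine: bool = False,
) -> float:
    """-log( e^{s(a,p)/τ} / (e^{s(a,p)/τ} + Σ_n e^{s(a,n)/τ}) ), stabilised.

    With zero negatives the ratio is 1 and the loss is exactly 0.
    """
    anchor = np.asarray(anchor, dtype=float)
    pos_logit = float(_sim(anchor, np.asarray(positive, dtype=float), cosine)) / temperature
    if len(negatives) == 0:
        return 0.0
    neg = np.asarray(negatives, dtype=float)
    neg_logits = _sim(anchor, neg, cosine) / temperature
    all_logits = np.concatenate([[pos_logit], np.atleast_1d(neg_logits)])
    return float(logsumexp(all_logits) - pos_logit)


def intra_loss(
    local: Mapping[object, LayerEmbeddings],
    nonlocal_: Mapping[object, LayerEmbeddings],
    config: ContrastiveConfig,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Intra-graph contrastive loss summed over anchors and both contexts.

    Per anchor and context: anchor vector = layer 0, positive = layer 1,
    negatives = up to ``negatives_per_anchor`` uniformly sampled layers
    ``l ≥ 2``.  With fewer than 3 layers there are no valid negatives and
    the anchor contributes the zero-negative value (0).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    total = 0.0
    for key in local:
        for embs in (local[key], nonlocal_[key]):
            vecs = embs.vectors
            n_layers = len(vecs)  # L+1
            if n_layers < 2:
                continue
            candidates = np.arange(2, n_layers)
            if len(candidates) > config.negatives_per_anchor:
                chosen = rng.choice(candidates, size=config.negatives_per_anchor, replace=False)
            else:
                chosen = candidates
            total += infonce(
                vecs[0], vecs[1], [vecs[j] for j in chosen], config.temperature, config.cosine
            )
    return total


def inter_loss(
    local: Mapping[object, LayerEmbeddings],
    nonlocal_: Mapping[object, LayerEmbeddings],
    config: ContrastiveConfig,
) -> float:
    """Inter-graph contrastive loss summed over anchors and layers.

    For each anchor and layer k: anchor = local layer-k vector, positive =
    non-local layer-k vector, negatives = non-local layers k' ≠ k.
    """
    total = 0.0
    for key in local:
        lv = local[key].vectors
        nv = nonlocal_[key].vectors
        if lv.shape != nv.shape:
            raise ValueError("local and non-local embeddings must have matching shapes")
        n_layers = len(lv)
        for k in range(n_layers):
            negs = [nv[j] for j in range(n_layers) if j != k]
            total += infonce(lv[k], nv[k], negs, config.temperature, config.cosine)
    return total


def combined_ssl(intra: float, inter: float, config: ContrastiveConfig) -> float:
    """Weighted self-supervised term: intra_weight·intra + inter_weight·inter."""
    return config.intra_weight * intra + config.inter_weight * inter
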