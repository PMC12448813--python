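"""Layered local / non-local graph construction per anchor node.

For every anchor (a microbe or a drug) two layered structures are built:

* the **local** graph, seeded by the anchor's aligned entity plus the
  aligned entities of its direct interaction partners (first-order
  collaborative-filtering signal), and
* the **non-local** graph, seeded by the aligned entities of its high-order
  partners — the drugs interacted with by similar microbes (or, mirrored,
  the microbes interacting with similar drugs) excluding the anchor's own
  direct partners.

Each seed set is then expanded through the knowledge graph for ``L`` hops:
layer ``l`` collects every triple whose head lies in the entity set of layer
``l − 1`` (optionally subsampled to a per-layer budget), and the layer's
entity set is the collection of retained tails.  Propagation follows edge
direction head → tail; call :meth:`KnowledgeGraph.with_inverse_relations`
first if undirected traversal is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .data import EntityAlignment, InteractionMatrix, KnowledgeGraph

__all__ = [
    "NodeRef",
    "LayeredEntitySets",
    "LayeredTripleSets",
    "direct_counterparts",
    "local_seed_entities",
    "similar_microbes",
    "similar_drugs",
    "high_order_drugs",
    "high_order_microbes",
    "nonlocal_seed_entities",
    "propagate",
    "build_all_graphs",
]

Side = Literal["microbe", "drug"]
Context = Literal["local", "nonlocal"]


class NodeRef(NamedTuple):
    """Reference to an anchor node on one side of the bipartite matrix."""

    side: Side
    index: int


@dataclass
class LayeredEntitySets:
    """Per-layer entity sets ``E^0 .. E^L`` (L+1 sets; layer 0 = seeds)."""

    anchor: NodeRef
    context: Context
    layers: list[set[int]]


@dataclass
class LayeredTripleSets:
    """Per-layer retained triple sets ``S^1 .. S^L`` (arrays of (h,r,t) rows)."""

    anchor: NodeRef
    context: Context
    layers: list[np.ndarray]


def direct_counterparts(anchor: NodeRef, im: InteractionMatrix) -> set[int]:
    """Indices on the opposite side with a known interaction with ``anchor``."""
    if anchor.side == "microbe":
        return set(np.flatnonzero(im.values[anchor.index]).tolist())
    return set(np.flatnonzero(im.values[:, anchor.index]).tolist())


def local_seed_entities(
    anchor: NodeRef, im: InteractionMatrix, alignment: EntityAlignment
) -> set[int]:
    """Layer-0 entity set of the local graph.

    The aligned entities of the anchor's direct counterparts, plus the
    anchor's own aligned entity (so isolated anchors still carry a layer-0
    representation).
    """
    if anchor.side == "microbe":
        own = alignment.microbe_to_entity[anchor.index]
        other = alignment.drug_to_entity
    else:
        own = alignment.drug_to_entity[anchor.index]
        other = alignment.microbe_to_entity
    seeds = {other[i] for i in direct_counterparts(anchor, im)}
    seeds.add(own)
    return seeds


def similar_microbes(anchor: int, im: InteractionMatrix) -> set[int]:
    """Microbes (excluding the anchor) sharing >=1 interacting drug with it."""
    row = im.values[anchor].astype(bool)
    if not row.any():
        return set()
    shares = (im.values[:, row].astype(bool)).any(axis=1)
    out = set(np.flatnonzero(shares).tolist())
    out.discard(anchor)
    return out


def similar_drugs(anchor: int, im: InteractionMatrix) -> set[int]:
    """Mirror of :func:`similar_microbes` for a drug anchor."""
    col = im.values[:, anchor].astype(bool)
    if not col.any():
        return set()
    shares = (im.values[col, :].astype(bool)).any(axis=0)
    out = set(np.flatnonzero(shares).tolist())
    out.discard(anchor)
    return out


def high_order_drugs(anchor: int, im: InteractionMatrix) -> set[int]:
    """Drugs of the anchor microbe's similar microbes, minus its own drugs."""
    sims = similar_microbes(anchor, im)
    if not sims:
        return set()
    mask = im.values[sorted(sims), :].astype(bool).any(axis=0)
    drugs = set(np.flatnonzero(mask).tolist())
    return drugs - direct_counterparts(NodeRef("microbe", anchor), im)


def high_order_microbes(anchor: int, im: InteractionMatrix) -> set[int]:
    """Mirror of :func:`high_order_drugs` for a drug anchor."""
    sims = similar_drugs(anchor, im)
    if not sims:
        return set()
    mask = im.values[:, sorted(sims)].astype(bool).any(axis=1)
    microbes = set(np.flatnonzero(mask).tolist())
    return microbes - direct_counterparts(NodeRef("drug", anchor), im)


def nonlocal_seed_entities(
    anchor: NodeRef, im: InteractionMatrix, alignment: EntityAlignment
) -> set[int]:
    """Layer-0 entity set of the non-local graph (may be empty)."""
    if anchor.side == "microbe":
        return {alignment.drug_to_entity[d] for d in high_order_drugs(anchor.index, im)}
    return {alignment.microbe_to_entity[m] for m in high_order_microbes(anchor.index, im)}


def propagate(
    kg: KnowledgeGraph,
    seeds: set[int],
    n_layers: int,
    budget: int | None = None,
    rng: np.random.Generator | int | None = None,
    anchor: NodeRef = NodeRef("microbe", 0),
    context: Context = "local",
) -> tuple[LayeredTripleSets, LayeredEntitySets]:
    """Expand a seed entity set through the KG for ``n_layers`` hops.

    Layer ``l`` gathers all triples with head in layer ``l − 1``'s entity
    set, uniformly subsampled without replacement to at most ``budget``
    triples (``budget=None`` keeps all); the layer's entity set is the set
    of retained tails.  An empty frontier yields empty deeper layers.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if budget is not None and budget < 1:
        raise ValueError("budget must be >= 1 (or None for unlimited)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    entity_layers: list[set[int]] = [set(seeds)]
    triple_layers: list[np.ndarray] = []
    frontier = sorted(seeds)
    empty = np.empty((0, 3), dtype=np.int64)
    for _ in range(n_layers):
        if frontier:
            chunks = [kg.head_index[h] for h in frontier if h in kg.head_index]
        else:
            chunks = []
        if chunks:
            rt = np.vstack(chunks)
            heads = np.concatenate(
                [np.full(len(kg.head_index[h]), h, dtype=np.int64) for h in frontier if h in kg.head_index]
            )
            layer = np.column_stack([heads, rt])
            if budget is not None and len(layer) > budget:
                keep = rng.choice(len(layer), size=budget, replace=False)
                layer = layer[np.sort(keep)]
        else:
            layer = empty
        triple_layers.append(layer)
        tails = set(layer[:, 2].tolist()) if len(layer) else set()
        entity_layers.append(tails)
        frontier = sorted(tails)
    return (
        LayeredTripleSets(anchor, context, triple_layers),
        LayeredEntitySets(anchor, context, entity_layers),
    )


def build_all_graphs(
    kg: KnowledgeGraph,
    im: InteractionMatrix,
    alignment: EntityAlignment,
    n_layers: int,
    budget: int | None,
    seed: int | None = 0,
) -> dict[tuple[Side, int, Context], tuple[LayeredTripleSets, LayeredEntitySets]]:
    """Build local and non-local layered structures for every anchor.

    Deterministic given ``seed``: each (anchor, context) gets its own RNG
    stream derived from the seed, so results do not depend on iteration
    order.
    """
    out: dict[tuple[Side, int, Context], tuple[LayeredTripleSets, LayeredEntitySets]] = {}
    sides: list[tuple[Side, int]] = [("microbe", im.n_microbes), ("drug", im.n_drugs)]
    for side_id, (side, count) in enumerate(sides):
        for idx in range(count):
            anchor = NodeRef(side, idx)
            for ctx_id, ctx in enumerate(("local", "nonlocal")):
                if ctx == "local":
                    seeds = local_seed_entities(anchor, im, alignment)
                else:
                    seeds = nonlocal_seed_entities(anchor, im, alignment)
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(2, side_id, idx, ctx_id))
                )
                out[(side, idx, ctx)] = propagate(
                    kg, seeds, n_layers, budget, rng, anchor=anchor, context=ctx
                )
    return out
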