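"""Synthetic benchmark generator with a planted low-rank association signal.

The generator emulates the situation the predictor is built for: a sparse
binary microbe × drug matrix whose ones arise from a shared low-dimensional
latent structure, together with a knowledge graph whose relational structure
encodes that same structure through shared *attribute* entities (one entity
per microbe and per drug, plus attribute entities carrying latent
directions).  Because the interaction decoder of the model is a
dot-product-plus-sigmoid, a logistic low-rank generative model makes signal
recovery a fair measurement surface.

The default :class:`SyntheticSpec` is the benchmark configuration used
throughout the test-suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .data import EntityAlignment, InteractionMatrix, KnowledgeGraph

__all__ = ["SyntheticSpec", "generate_interactions", "generate_kg", "make_benchmark"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-signal benchmark.

    Attributes
    ----------
    n_microbes, n_drugs
        Interaction-matrix dimensions.
    latent_rank
        Rank of the planted factor model (U is n_microbes × rank,
        V is n_drugs × rank, standard normal entries).
    interaction_density
        Target expected fraction of ones in the matrix; the logistic bias is
        solved numerically so the expectation matches.
    signal_scale
        Multiplier ``s`` on the latent dot product inside the logistic link;
        controls how separable the planted signal is.
    n_attribute_entities
        Number of extra KG entities carrying latent directions.
    n_relations
        Number of distinct KG relation types.
    kg_edges_per_node
        Number of attribute links per microbe/drug node (each link is
        emitted in both directions so propagation can traverse
        node—attribute—node paths).
    attribute_noise
        Fraction of attribute links rewired to a uniformly random attribute
        entity, destroying the encoded signal at 1.0.
    seed
        Seed for all randomness in the generator.
    """

    n_microbes: int = 100
    n_drugs: int = 200
    latent_rank: int = 4
    interaction_density: float = 0.05
    signal_scale: float = 2.0
    n_attribute_entities: int = 300
    n_relations: int = 5
    kg_edges_per_node: int = 6
    attribute_noise: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if not (0.0 < self.interaction_density < 1.0):
            raise ValueError("interaction_density must lie in (0, 1)")
        if not (0.0 <= self.attribute_noise <= 1.0):
            raise ValueError("attribute_noise must lie in [0, 1]")
        if self.n_microbes < 1 or self.n_drugs < 1:
            raise ValueError("need at least one microbe and one drug")
        if self.n_relations < 1 or self.kg_edges_per_node < 1:
            raise ValueError("n_relations and kg_edges_per_node must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LatentFactors:
    """Planted factors returned for downstream correlation checks."""

    microbes: np.ndarray  # (n_microbes, rank)
    drugs: np.ndarray  # (n_drugs, rank)
    bias: float


def _solve_bias(logits: np.ndarray, density: float) -> float:
    """Bias b with mean(sigmoid(logits + b)) == density, by bisection."""

    def gap(b: float) -> float:
        return float(expit(logits + b).mean() - density)

    # bracket must scale with the logit spread so extreme signal scales
    # (near-deterministic matrices) still admit a threshold-style bias
    span = float(np.abs(logits).max()) + 60.0
    lo, hi = -span, span
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError("cannot bracket the requested interaction density")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def generate_interactions(spec: SyntheticSpec) -> tuple[InteractionMatrix, LatentFactors]:
    """Draw the binary matrix from the logistic low-rank model.

    Entry ``(i, j)`` is 1 with probability ``sigmoid(s * U_i . V_j + b)``
    where ``b`` is solved so the expected density equals
    ``spec.interaction_density``.  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    U = rng.standard_normal((spec.n_microbes, spec.latent_rank))
    V = rng.standard_normal((spec.n_drugs, spec.latent_rank))
    logits = spec.signal_scale * (U @ V.T)
    bias = _solve_bias(logits, spec.interaction_density)
    probs = expit(logits + bias)
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    im = InteractionMatrix(
        values,
        [f"m{i}" for i in range(spec.n_microbes)],
        [f"d{j}" for j in range(spec.n_drugs)],
    )
    return im, LatentFactors(U, V, bias)


def generate_kg(
    spec: SyntheticSpec,
    factors: LatentFactors,
    attribute_directions: np.ndarray | None = None,
) -> tuple[KnowledgeGraph, EntityAlignment]:
    """Build a KG whose attribute links encode the planted factors.

    Entities are one per microbe, one per drug, plus
    ``spec.n_attribute_entities`` attribute entities, each holding a unit
    latent direction (random by default, overridable for testing).  Every
    microbe/drug links to the ``kg_edges_per_node`` attribute entities whose
    directions best align with its factor vector; each link carries a
    relation drawn uniformly from the relation types and is emitted in both
    directions.  A fraction ``attribute_noise`` of links is rewired to a
    uniformly random attribute entity.
    """
    if spec.n_attribute_entities < spec.latent_rank:
        raise ValueError("n_attribute_entities must be >= latent_rank to encode the factors")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    n_m, n_d, n_a = spec.n_microbes, spec.n_drugs, spec.n_attribute_entities
    if attribute_directions is None:
        dirs = rng.standard_normal((n_a, spec.latent_rank))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    else:
        dirs = np.asarray(attribute_directions, dtype=float)
        if dirs.shape != (n_a, spec.latent_rank):
            raise ValueError("attribute_directions must be (n_attribute_entities, latent_rank)")

    entity_labels = (
        [f"m{i}" for i in range(n_m)]
        + [f"d{j}" for j in range(n_d)]
        + [f"attr{k}" for k in range(n_a)]
    )
    relation_labels = [f"rel{r}" for r in range(spec.n_relations)]
    node_factors = np.vstack([factors.microbes, factors.drugs])
    n_nodes = n_m + n_d
    k = min(spec.kg_edges_per_node, n_a)

    align = dirs @ node_factors.T  # (n_a, n_nodes)
    # top-k attribute entities per node by alignment (deterministic ties by index)
    top = np.argsort(-align, axis=0, kind="stable")[:k, :]  # (k, n_nodes)

    triples: list[tuple[int, int, int]] = []
    for node in range(n_nodes):
        node_ent = node
        targets = top[:, node].copy()
        rewire = rng.random(k) < spec.attribute_noise
        targets[rewire] = rng.integers(0, n_a, size=int(rewire.sum()))
        relations = rng.integers(0, spec.n_relations, size=k)
        for attr, rel in zip(targets, relations):
            attr_ent = n_nodes + int(attr)
            triples.append((node_ent, int(rel), attr_ent))
            triples.append((attr_ent, int(rel), node_ent))
    arr = np.array(sorted(set(triples)), dtype=np.int64)
    kg = KnowledgeGraph(arr, entity_labels, relation_labels)
    alignment = EntityAlignment(
        {i: i for i in range(n_m)},
        {j: n_m + j for j in range(n_d)},
    )
    return kg, alignment


def make_benchmark(
    spec: SyntheticSpec | None = None,
) -> tuple[KnowledgeGraph, InteractionMatrix, EntityAlignment, np.ndarray]:
    """Generate the full benchmark bundle.

    Returns the KG, the interaction matrix, the alignment, and the
    deterministic (row-major) list of all positive pairs used for fold
    splitting.
    """
    spec = spec if spec is not None else SyntheticSpec()
    im, factors = generate_interactions(spec)
    kg, alignment = generate_kg(spec, factors)
    return kg, im, alignment, im.positive_pairs()
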