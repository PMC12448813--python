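import numpy as np
import pytest

from kglink.data import EntityAlignment, InteractionMatrix, KnowledgeGraph
from kglink.synthetic import SyntheticSpec, make_benchmark


@pytest.fixture
def chain_kg() -> KnowledgeGraph:
    """a -R-> b -R-> c."""
    return KnowledgeGraph(
        np.array([[0, 0, 1], [1, 0, 2]]), ["a", "b", "c"], ["R"]
    )


@pytest.fixture
def tiny_dataset():
    """Small planted-signal dataset exercising the whole pipeline quickly."""
    spec = SyntheticSpec(
        n_microbes=15, n_drugs=20, latent_rank=2, interaction_density=0.15,
        n_attribute_entities=30, kg_edges_per_node=4, seed=11,
    )
    kg, im, alignment, positives = make_benchmark(spec)
    return kg, im, alignment, positives


def random_kg(rng: np.random.Generator, n_entities=50, n_relations=5, n_triples=200):
    """Random KG with unique triples, for oracle comparisons."""
    seen = set()
    while len(seen) < n_triples:
        h, r, t = (
            int(rng.integers(n_entities)),
            int(rng.integers(n_relations)),
            int(rng.integers(n_entities)),
        )
        seen.add((h, r, t))
    arr = np.array(sorted(seen), dtype=np.int64)
    return KnowledgeGraph(
        arr, [f"e{i}" for i in range(n_entities)], [f"r{i}" for i in range(n_relations)]
    )


def random_interactions(rng: np.random.Generator, n_m=20, n_d=30, density=0.2):
    values = (rng.random((n_m, n_d)) < density).astype(np.int8)
    return InteractionMatrix(
        values, [f"m{i}" for i in range(n_m)], [f"d{j}" for j in range(n_d)]
    )
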