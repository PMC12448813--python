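"""Loading, validation, indexing and serialization of the three core inputs.

A dataset is a triple of objects:

* :class:`KnowledgeGraph` — an integer-indexed triple store ``{(h, r, t)}``
  over biomedical entities, with a head-indexed adjacency used by the layered
  propagation in :mod:`kglink.graphs`.
* :class:`InteractionMatrix` — the binary microbe × drug matrix ``A`` whose
  ones are the known (validated) microbe–drug associations.
* :class:`EntityAlignment` — the map taking every microbe and drug of the
  interaction matrix to its entity in the knowledge graph.

All on-disk formats are plain TSV; labels are case-sensitive and never
normalized, and internal indices are dense and 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "InteractionMatrix",
    "EntityAlignment",
    "ValidationReport",
    "read_triples",
    "write_triples",
    "read_interactions",
    "write_interactions",
    "read_alignment",
    "write_alignment",
    "identity_alignment",
    "validate_dataset",
]


class Triple(NamedTuple):
    """A single ``(head, relation, tail)`` fact, as dense 0-based indices."""

    head: int
    relation: int
    tail: int


def _build_head_index(triples: np.ndarray, entity_count: int) -> dict[int, np.ndarray]:
    """Group triples by head entity: head -> array of (relation, tail) rows."""
    index: dict[int, np.ndarray] = {}
    if len(triples) == 0:
        return index
    order = np.argsort(triples[:, 0], kind="stable")
    sorted_t = triples[order]
    heads, starts = np.unique(sorted_t[:, 0], return_index=True)
    bounds = np.append(starts, len(sorted_t))
    for i, h in enumerate(heads):
        index[int(h)] = sorted_t[bounds[i] : bounds[i + 1], 1:3]
    return index


@dataclass
class KnowledgeGraph:
    """Integer-indexed knowledge graph with label maps and head adjacency.

    Parameters
    ----------
    triples
        ``(n, 3)`` integer array of ``(head, relation, tail)`` rows, free of
        duplicates.
    entity_labels, relation_labels
        Dense index → string label, in first-appearance order of the source.
    """

    triples: np.ndarray
    entity_labels: list[str]
    relation_labels: list[str]
    head_index: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.triples = np.asarray(self.triples, dtype=np.int64).reshape(-1, 3)
        if len(self.triples):
            if self.triples[:, [0, 2]].max() >= self.entity_count:
                raise ValueError("triple references entity index out of range")
            if self.triples[:, 1].max() >= self.relation_count:
                raise ValueError("triple references relation index out of range")
            if self.triples.min() < 0:
                raise ValueError("negative index in triples")
        if not self.head_index:
            self.head_index = _build_head_index(self.triples, self.entity_count)

    @property
    def entity_count(self) -> int:
        return len(self.entity_labels)

    @property
    def relation_count(self) -> int:
        return len(self.relation_labels)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def iter_triples(self) -> Iterable[Triple]:
        for h, r, t in self.triples:
            yield Triple(int(h), int(r), int(t))

    def entity_id(self, label: str) -> int:
        try:
            return self._entity_lookup[label]
        except AttributeError:
            self._entity_lookup = {lab: i for i, lab in enumerate(self.entity_labels)}
            return self._entity_lookup[label]

    def with_inverse_relations(self) -> "KnowledgeGraph":
        """Return a graph where every relation also has an explicit inverse.

        For each relation ``R`` a relation ``R._inv`` is added, and for every
        triple ``(h, R, t)`` the triple ``(t, R._inv, h)`` is inserted.  Used
        when propagation should be able to walk edges against their direction.
        """
        n_rel = self.relation_count
        inv = self.triples[:, [2, 1, 0]].copy()
        inv[:, 1] += n_rel
        merged = np.unique(np.vstack([self.triples, inv]), axis=0)
        labels = list(self.relation_labels) + [f"{r}._inv" for r in self.relation_labels]
        return KnowledgeGraph(merged, list(self.entity_labels), labels)

    def out_degrees(self) -> np.ndarray:
        deg = np.zeros(self.entity_count, dtype=np.int64)
        if len(self.triples):
            heads, counts = np.unique(self.triples[:, 0], return_counts=True)
            deg[heads] = counts
        return deg


@dataclass
class InteractionMatrix:
    """Binary microbe × drug association matrix with label maps."""

    values: np.ndarray
    microbe_labels: list[str]
    drug_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("interaction matrix must be 2-D")
        if self.values.shape != (len(self.microbe_labels), len(self.drug_labels)):
            raise ValueError("matrix shape does not match label counts")
        if self.n_microbes < 1 or self.n_drugs < 1:
            raise ValueError("need at least one microbe and one drug")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")

    @property
    def n_microbes(self) -> int:
        return self.values.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.values.shape[1]

    def positive_pairs(self) -> np.ndarray:
        """All ``(microbe, drug)`` index pairs with a known association,
        in row-major order (deterministic)."""
        m, d = np.nonzero(self.values)
        return np.column_stack([m, d]).astype(np.int64)


@dataclass
class EntityAlignment:
    """Total maps from microbe/drug indices to KG entity indices."""

    microbe_to_entity: dict[int, int]
    drug_to_entity: dict[int, int]

    def microbe_entities(self) -> np.ndarray:
        return np.array([self.microbe_to_entity[i] for i in range(len(self.microbe_to_entity))])

    def drug_entities(self) -> np.ndarray:
        return np.array([self.drug_to_entity[i] for i in range(len(self.drug_to_entity))])


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_triples(path: str | Path) -> KnowledgeGraph:
    """Read a 3-column TSV triple file (``head␉relation␉tail``).

    ``#`` comment lines are skipped.  Labels are interned to dense 0-based
    indices in first-appearance order; exact duplicate triples are dropped
    (logged at debug).  Columns beyond the first three are ignored.
    """
    path = Path(path)
    entity_ids: dict[str, int] = {}
    relation_ids: dict[str, int] = {}
    rows: list[tuple[int, int, int]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}")
        h_lab, r_lab, t_lab = fields[0], fields[1], fields[2]
        h = entity_ids.setdefault(h_lab, len(entity_ids))
        r = relation_ids.setdefault(r_lab, len(relation_ids))
        t = entity_ids.setdefault(t_lab, len(entity_ids))
        rows.append((h, r, t))
    if rows:
        # dedup preserving first-appearance order
        seen: dict[tuple[int, int, int], None] = {}
        for row in rows:
            seen.setdefault(row, None)
        arr = np.array(list(seen), dtype=np.int64)
        if len(arr) < len(rows):
            logger.debug("dropped %d duplicate triples from %s", len(rows) - len(arr), path)
    else:
        arr = np.empty((0, 3), dtype=np.int64)
    return KnowledgeGraph(arr, list(entity_ids), list(relation_ids))


def write_triples(kg: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h, r, t in kg.triples:
            fh.write(f"{kg.entity_labels[h]}\t{kg.relation_labels[r]}\t{kg.entity_labels[t]}\n")


def read_interactions(path: str | Path, format: str = "auto") -> InteractionMatrix:
    """Read an interaction table.

    ``edge-list`` rows are ``microbe␉drug[␉value]`` with value defaulting
    to 1; label order is first appearance.  ``dense`` is a TSV matrix with a
    header row of drug labels and a first column of microbe labels (the only
    form that can represent isolated microbes/drugs).  ``auto`` sniffs: a
    first line starting with a tab (the dense format's empty corner cell)
    selects dense.
    """
    path = Path(path)
    if format == "auto":
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        format = "dense" if first.startswith("\t") else "edge-list"
    if format == "dense":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        values = frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"{path}: non-binary value in dense interaction matrix")
        return InteractionMatrix(
            values.astype(np.int8),
            [str(x) for x in frame.index],
            [str(x) for x in frame.columns],
        )
    if format != "edge-list":
        raise ValueError(f"unknown interaction format: {format!r}")

    microbes: dict[str, int] = {}
    drugs: dict[str, int] = {}
    entries: dict[tuple[int, int], int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected at least 2 fields")
        value = 1
        if len(fields) >= 3 and fields[2] != "":
            if fields[2] not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: non-binary value {fields[2]!r}")
            value = int(fields[2])
        m = microbes.setdefault(fields[0], len(microbes))
        d = drugs.setdefault(fields[1], len(drugs))
        if (m, d) in entries and entries[(m, d)] != value:
            raise ValueError(f"{path}:{lineno}: conflicting duplicate for ({fields[0]}, {fields[1]})")
        entries[(m, d)] = value
    if not microbes or not drugs:
        raise ValueError(f"{path}: empty edge list — no microbes/drugs inferable")
    values = np.zeros((len(microbes), len(drugs)), dtype=np.int8)
    for (m, d), v in entries.items():
        values[m, d] = v
    return InteractionMatrix(values, list(microbes), list(drugs))


def write_interactions(im: InteractionMatrix, path: str | Path, format: str = "edge-list") -> None:
    if format == "dense":
        frame = pd.DataFrame(im.values, index=im.microbe_labels, columns=im.drug_labels)
        frame.to_csv(path, sep="\t")
        return
    if format != "edge-list":
        raise ValueError(f"unknown interaction format: {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        for m, d in im.positive_pairs():
            fh.write(f"{im.microbe_labels[m]}\t{im.drug_labels[d]}\n")


def read_alignment(path: str | Path, kg: KnowledgeGraph, im: InteractionMatrix) -> EntityAlignment:
    """Read a 2-column TSV (``node-label␉entity-label``) alignment.

    Every microbe and drug label of ``im`` must appear exactly once; entity
    labels must exist in ``kg``.  Unmapped KG entities (attribute entities)
    are allowed.
    """
    path = Path(path)
    entity_lookup = {lab: i for i, lab in enumerate(kg.entity_labels)}
    microbe_lookup = {lab: i for i, lab in enumerate(im.microbe_labels)}
    drug_lookup = {lab: i for i, lab in enumerate(im.drug_labels)}
    m2e: dict[int, int] = {}
    d2e: dict[int, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields")
        node_lab, ent_lab = fields[0], fields[1]
        if ent_lab not in entity_lookup:
            raise ValueError(f"{path}:{lineno}: unknown KG entity label {ent_lab!r}")
        ent = entity_lookup[ent_lab]
        matched = False
        if node_lab in microbe_lookup:
            idx = microbe_lookup[node_lab]
            if idx in m2e:
                raise ValueError(f"{path}:{lineno}: duplicate alignment row for microbe {node_lab!r}")
            m2e[idx] = ent
            matched = True
        if node_lab in drug_lookup:
            idx = drug_lookup[node_lab]
            if idx in d2e:
                raise ValueError(f"{path}:{lineno}: duplicate alignment row for drug {node_lab!r}")
            d2e[idx] = ent
            matched = True
        if not matched:
            raise ValueError(f"{path}:{lineno}: label {node_lab!r} is neither a microbe nor a drug")
    missing_m = [im.microbe_labels[i] for i in range(im.n_microbes) if i not in m2e]
    missing_d = [im.drug_labels[i] for i in range(im.n_drugs) if i not in d2e]
    if missing_m or missing_d:
        raise ValueError(f"alignment missing microbes {missing_m} and drugs {missing_d}")
    return EntityAlignment(m2e, d2e)


def write_alignment(
    alignment: EntityAlignment, kg: KnowledgeGraph, im: InteractionMatrix, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(im.n_microbes):
            fh.write(f"{im.microbe_labels[i]}\t{kg.entity_labels[alignment.microbe_to_entity[i]]}\n")
        for j in range(im.n_drugs):
            fh.write(f"{im.drug_labels[j]}\t{kg.entity_labels[alignment.drug_to_entity[j]]}\n")


def identity_alignment(kg: KnowledgeGraph, im: InteractionMatrix) -> EntityAlignment:
    """Alignment for datasets where microbes/drugs *are* KG entities
    (microbe/drug labels equal entity labels)."""
    lookup = {lab: i for i, lab in enumerate(kg.entity_labels)}
    try:
        m2e = {i: lookup[lab] for i, lab in enumerate(im.microbe_labels)}
        d2e = {j: lookup[lab] for j, lab in enumerate(im.drug_labels)}
    except KeyError as exc:  # pragma: no cover - message path
        raise ValueError(f"label {exc.args[0]!r} not present among KG entities") from exc
    return EntityAlignment(m2e, d2e)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Report-only summary of a loaded dataset (never raises)."""

    n_microbes: int
    n_drugs: int
    n_positive_edges: int
    isolated_microbes: list[int]
    isolated_drugs: list[int]
    kg_entity_count: int
    kg_triple_count: int
    kg_degree_summary: dict[str, float]
    structural_errors: list[str]

    def __str__(self) -> str:
        lines = [
            f"interactions: {self.n_microbes} microbes x {self.n_drugs} drugs, "
            f"{self.n_positive_edges} positives",
            f"isolated microbes: {len(self.isolated_microbes)}, "
            f"isolated drugs: {len(self.isolated_drugs)}",
            f"KG: {self.kg_entity_count} entities, {self.kg_triple_count} triples, "
            f"out-degree min/median/max = "
            f"{self.kg_degree_summary['min']:.0f}/"
            f"{self.kg_degree_summary['median']:.1f}/"
            f"{self.kg_degree_summary['max']:.0f}",
        ]
        if self.structural_errors:
            lines.append("structural errors: " + "; ".join(self.structural_errors))
        return "\n".join(lines)


def validate_dataset(
    kg: KnowledgeGraph, im: InteractionMatrix, alignment: EntityAlignment
) -> ValidationReport:
    """Summarise a dataset and flag structural problems without raising."""
    errors: list[str] = []
    for name, mapping, count in (
        ("microbe", alignment.microbe_to_entity, im.n_microbes),
        ("drug", alignment.drug_to_entity, im.n_drugs),
    ):
        if set(mapping) != set(range(count)):
            errors.append(f"{name} alignment is not total")
        bad = [e for e in mapping.values() if not (0 <= e < kg.entity_count)]
        if bad:
            errors.append(f"{name} alignment references invalid entities {bad}")
    deg = kg.out_degrees()
    summary = {
        "min": float(deg.min()) if len(deg) else 0.0,
        "median": float(np.median(deg)) if len(deg) else 0.0,
        "max": float(deg.max()) if len(deg) else 0.0,
        "mean": float(deg.mean()) if len(deg) else 0.0,
    }
    return ValidationReport(
        n_microbes=im.n_microbes,
        n_drugs=im.n_drugs,
        n_positive_edges=int(im.values.sum()),
        isolated_microbes=[int(i) for i in np.flatnonzero(im.values.sum(axis=1) == 0)],
        isolated_drugs=[int(j) for j in np.flatnonzero(im.values.sum(axis=0) == 0)],
        kg_entity_count=kg.entity_count,
        kg_triple_count=kg.n_triples,
        kg_degree_summary=summary,
        structural_errors=errors,
    )
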