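"""Core domain containers shared across the pipeline.

Identifier handling: every entity id (miRNA, disease, gene) is normalized —
lowercased, stripped, internal whitespace collapsed — before registration, so
name variants such as ``miR-21`` / ``mir-21`` resolve to one entity.  No fuzzy
matching is attempted; callers may supply an explicit raw→canonical mapping.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

_WS = re.compile(r"\s+")


def normalize_id(raw: str, mapping: Mapping[str, str] | None = None) -> str:
    """Normalize an identifier string (lowercase, trim, collapse whitespace).

    If ``mapping`` is given, the normalized id is translated through it (the
    mapping's keys and values are themselves normalized on lookup).
    """
    norm = _WS.sub(" ", raw.strip()).lower()
    if mapping is not None and norm in mapping:
        norm = _WS.sub(" ", mapping[norm].strip()).lower()
    return norm


@dataclass(frozen=True)
class EntityRegistry:
    """Ordered, deduplicated id namespace for one entity kind.

    Ordering is lexicographic on the normalized ids so that every matrix
    built against the registry is reproducible across runs and platforms.
    """

    kind: str
    ids: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False)

    @classmethod
    def from_ids(cls, kind: str, ids: Iterable[str]) -> "EntityRegistry":
        ordered = tuple(sorted(set(ids)))
        return cls(kind=kind, ids=ordered, index={e: k for k, e in enumerate(ordered)})

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.index


@dataclass
class AssociationTable:
    """Binary miRNA x disease association matrix with its id registries."""

    mirnas: EntityRegistry
    diseases: EntityRegistry
    A: np.ndarray  # shape (m, d), dtype int8, entries in {0, 1}

    def __post_init__(self) -> None:
        m, d = len(self.mirnas), len(self.diseases)
        if self.A.shape != (m, d):
            raise ValueError(f"association matrix shape {self.A.shape} != ({m}, {d})")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix must be binary")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]]
    ) -> "AssociationTable":
        uniq = sorted(set(pairs))
        if not uniq:
            raise ValueError("no associations parsed")
        mirnas = EntityRegistry.from_ids("miRNA", (p[0] for p in uniq))
        diseases = EntityRegistry.from_ids("disease", (p[1] for p in uniq))
        A = np.zeros((len(mirnas), len(diseases)), dtype=np.int8)
        for mi, di in uniq:
            A[mirnas.index[mi], diseases.index[di]] = 1
        return cls(mirnas=mirnas, diseases=diseases, A=A)

    @property
    def n_positive(self) -> int:
        return int(self.A.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        return [tuple(ij) for ij in np.argwhere(self.A == 1)]


@dataclass
class InteractionTable:
    """Deduplicated (entity, gene) annotation pairs for one entity kind.

    The deduplicated pair count is the corpus size N that normalizes gene
    frequencies in the entropy computation.
    """

    entity_kind: str
    pairs: tuple[tuple[str, str], ...]
    entities: EntityRegistry
    genes: EntityRegistry

    @classmethod
    def from_pairs(
        cls, entity_kind: str, pairs: Iterable[tuple[str, str]]
    ) -> "InteractionTable":
        uniq = tuple(sorted(set(pairs)))
        entities = EntityRegistry.from_ids(entity_kind, (p[0] for p in uniq))
        genes = EntityRegistry.from_ids("gene", (p[1] for p in uniq))
        return cls(entity_kind=entity_kind, pairs=uniq, entities=entities, genes=genes)

    @property
    def n_interactions(self) -> int:
        return len(self.pairs)


@dataclass
class SimilarityMatrix:
    """Square symmetric entity-by-entity similarity with values in [0, 1]."""

    registry: EntityRegistry
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.registry)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.registry.index[entity_id]]
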