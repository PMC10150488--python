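"""Readers and writers for the tabular inputs and outputs.

All files are plain TSV.  Lines starting with ``#`` are comments and are
skipped by every reader; ids in files are normalized on read (see
:mod:`mirvote.containers`) while written files keep whatever id strings the
caller passes in.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AssociationTable,
    EntityRegistry,
    InteractionTable,
    SimilarityMatrix,
    normalize_id,
)

#: tolerance beyond which out-of-range / asymmetric similarity entries are
#: reported rather than silently repaired
_TOL = 1e-9


class ParseError(ValueError):
    pass


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column raw→canonical id mapping file."""
    mapping: dict[str, str] = {}
    for lineno, fields in _iter_tsv(path, min_fields=2):
        mapping[normalize_id(fields[0])] = fields[1]
    return mapping


def _iter_tsv(path: str | Path, min_fields: int):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_fields} tab-separated "
                    f"fields, got {len(fields)}"
                )
            yield lineno, fields


def read_associations(
    path: str | Path, mapping: Mapping[str, str] | None = None
) -> AssociationTable:
    """Read a two-column (miRNA, disease) TSV into an association matrix.

    Duplicate pairs collapse to a single 1-entry; row/column order is the
    registries' deterministic lexicographic order.
    """
    pairs = [
        (normalize_id(f[0], mapping), normalize_id(f[1], mapping))
        for _, f in _iter_tsv(path, min_fields=2)
    ]
    if not pairs:
        raise ParseError(f"{path}: no associations parsed")
    return AssociationTable.from_pairs(pairs)


def read_interactions(
    path: str | Path,
    entity_kind: str,
    mapping: Mapping[str, str] | None = None,
) -> InteractionTable:
    """Read a two-column (entity, gene) TSV; duplicates collapse to one pair."""
    pairs = [
        (normalize_id(f[0], mapping), normalize_id(f[1], mapping))
        for _, f in _iter_tsv(path, min_fields=2)
    ]
    return InteractionTable.from_pairs(entity_kind, pairs)


def read_similarity_matrix(
    path: str | Path, kind: str = "entity", mapping: Mapping[str, str] | None = None
) -> SimilarityMatrix:
    """Read a square TSV with matching header row and first column of ids.

    Values are clipped to [0, 1]; a clip beyond 1e-9 triggers a warning.
    Asymmetry beyond 1e-9 is an error; smaller asymmetry is averaged away.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: similarity matrix is not square {df.shape}")
    rows = [normalize_id(str(r), mapping) for r in df.index]
    cols = [normalize_id(str(c), mapping) for c in df.columns]
    if rows != cols:
        raise ParseError(f"{path}: header row and id column do not match")
    values = df.to_numpy(dtype=float)
    if np.abs(values - values.T).max(initial=0.0) > _TOL:
        raise ParseError(f"{path}: matrix is asymmetric beyond {_TOL}")
    values = (values + values.T) / 2.0
    if values.min(initial=0.0) < 0.0 or values.max(initial=1.0) > 1.0:
        warnings.warn(f"{path}: similarity values outside [0, 1] were clipped")
    values = np.clip(values, 0.0, 1.0)
    registry = EntityRegistry.from_ids(kind, rows)
    order = np.array([rows.index(e) for e in registry.ids])
    return SimilarityMatrix(registry=registry, values=values[np.ix_(order, order)])


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(sim.values, index=sim.registry.ids, columns=sim.registry.ids)
    # %.17g keeps the write→read round trip lossless for float64
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_rankings(
    records: Sequence[tuple[str, str, float, bool]],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write ranked (miRNA, disease, score, known) records as TSV.

    Records are sorted by descending score with lexicographic (miRNA, disease)
    tie-breaks; rank is the 1-based position in that total order.
    """
    for mi, di, score, _known in records:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for pair ({mi}, {di})")
    ordered = sorted(records, key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("rank\tmiRNA\tdisease\tscore\tknown\n")
        for rank, (mi, di, score, known) in enumerate(ordered, start=1):
            fh.write(f"{rank}\t{mi}\t{di}\t{score:.10g}\t{int(known)}\n")


def read_rankings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for entity, gene in table.pairs:
            fh.write(f"{entity}\t{gene}\n")


def write_associations(assoc: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, j in assoc.positive_pairs():
            fh.write(f"{assoc.mirnas.ids[i]}\t{assoc.diseases.ids[j]}\n")
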