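"""Candidate scoring and ranking, including the isolated-disease protocol.

Standard mode trains on all known associations plus sampled negatives and
ranks the unknown pairs (globally or within one disease).  Isolated mode is
the cold-start setting: for a chosen disease every pair involving it is
removed from the positives and from the negative-sampling pool before
training, and all of its miRNA pairs are then scored, so no information about
that disease's column leaks into the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import AssociationTable, SimilarityMatrix
from .features import PcaModel, assemble_feature_table
from .learn import EnsembleSpec, TrainedEnsemble, build_training_set, train_ensemble
from .similarity import InteractionCorpus


@dataclass
class RankedPredictions:
    """Ranked candidate records: (rank, miRNA_id, disease_id, score, known)."""

    records: list[tuple[int, str, str, float, bool]]
    scope: str  # "global" or "disease:<id>"
    mode: str  # "standard" or "isolated"

    def top(self, k: int) -> "RankedPredictions":
        return RankedPredictions(self.records[:k], self.scope, self.mode)

    def as_write_records(self) -> list[tuple[str, str, float, bool]]:
        return [(mi, di, score, known) for _, mi, di, score, known in self.records]


def _rank(
    pairs: list[tuple[int, int]],
    scores: np.ndarray,
    assoc: AssociationTable,
    scope: str,
    mode: str,
) -> RankedPredictions:
    rows = [
        (assoc.mirnas.ids[i], assoc.diseases.ids[j], float(s), bool(assoc.A[i, j]))
        for (i, j), s in zip(pairs, scores)
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    records = [(k, mi, di, s, known) for k, (mi, di, s, known) in enumerate(rows, 1)]
    return RankedPredictions(records=records, scope=scope, mode=mode)


def score_candidates(
    model: TrainedEnsemble,
    assoc: AssociationTable,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    pca_models: tuple[PcaModel, PcaModel],
    mirna_corpus: InteractionCorpus,
    disease_corpus: InteractionCorpus,
    scope: str = "global",
    include_known: bool = False,
    top_k: int = 200,
    group_size: int = 50,
) -> RankedPredictions:
    """Score candidate pairs with the trained ensemble and rank them.

    ``scope`` is "global" (every pair) or "disease:<id>" (one disease's
    column).  Unless ``include_known`` is set, only unknown pairs
    (A(i,j) = 0) are ranked.
    """
    m, d = assoc.A.shape
    if scope == "global":
        cols = range(d)
    elif scope.startswith("disease:"):
        disease_id = scope.split(":", 1)[1]
        if disease_id not in assoc.diseases:
            raise KeyError(f"unknown disease: {disease_id}")
        cols = [assoc.diseases.index[disease_id]]
    else:
        raise ValueError(f"bad scope: {scope}")
    pairs = [
        (i, j)
        for j in cols
        for i in range(m)
        if include_known or assoc.A[i, j] == 0
    ]
    table = assemble_feature_table(
        pairs, None, SM, SD, pca_models, mirna_corpus, disease_corpus,
        top_k=top_k, group_size=group_size,
    )
    scores = model.predict_proba(table.values)
    return _rank(pairs, scores, assoc, scope, "standard")


def isolated_disease_run(
    disease_id: str,
    assoc: AssociationTable,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    pca_models: tuple[PcaModel, PcaModel],
    mirna_corpus: InteractionCorpus,
    disease_corpus: InteractionCorpus,
    spec: EnsembleSpec | None = None,
    seed: int = 0,
    neg_ratio: float = 1.0,
    top_k: int = 200,
    group_size: int = 50,
    exclude_negative_pool: bool = True,
) -> RankedPredictions:
    """Cold-start prediction for one disease.

    Training excludes every pair in the disease's column — positives always,
    and (by default) the negative-sampling pool as well, so no information
    about the column leaks; all m pairs (·, disease) are scored and ranked.
    """
    if disease_id not in assoc.diseases:
        raise KeyError(f"unknown disease: {disease_id}")
    j = assoc.diseases.index[disease_id]
    train = build_training_set(
        assoc, SM, SD, pca_models, mirna_corpus, disease_corpus,
        seed=seed, neg_ratio=neg_ratio, top_k=top_k, group_size=group_size,
        exclude_disease=j, exclude_negative_pool=exclude_negative_pool,
    )
    model = train_ensemble(train, spec)
    pairs = [(i, j) for i in range(assoc.A.shape[0])]
    table = assemble_feature_table(
        pairs, None, SM, SD, pca_models, mirna_corpus, disease_corpus,
        top_k=top_k, group_size=group_size,
    )
    scores = model.predict_proba(table.values)
    return _rank(pairs, scores, assoc, f"disease:{disease_id}", "isolated")


def annotate_with_lookup(
    preds: RankedPredictions, lookup: set[tuple[str, str]]
) -> list[tuple[int, str, str, float, bool, bool]]:
    """Flag each record against an external validation pair list."""
    return [
        (rank, mi, di, score, known, (mi, di) in lookup)
        for rank, mi, di, score, known in preds.records
    ]
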