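"""End-to-end composition of the prediction pipeline.

Wires the stages together: interaction corpora → NMI similarity matrices
(with the α-blend of semantic and functional disease similarity) → block PCA
→ training set → soft-voting ensemble.  The association table's registries
define the working miRNA/disease namespaces; entities with no gene
annotations keep empty sets and all-zero similarity rows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import AssociationTable, InteractionTable, SimilarityMatrix
from .features import PcaModel, fit_block_pca
from .learn import (
    CvReport,
    EnsembleSpec,
    TrainingSet,
    build_training_set,
    run_cross_validation,
)
from .similarity import (
    InteractionCorpus,
    build_corpus,
    functional_similarity_matrix,
    integrate_similarity,
    subset_similarity,
)


@dataclass
class PipelineContext:
    """Everything downstream stages need: similarities, PCA models, corpora."""

    assoc: AssociationTable
    SM: SimilarityMatrix
    SD: SimilarityMatrix
    pca_models: tuple[PcaModel, PcaModel]
    mirna_corpus: InteractionCorpus
    disease_corpus: InteractionCorpus
    alpha: float
    variance_threshold: float
    top_k: int
    group_size: int


def build_context(
    assoc: AssociationTable,
    mirna_interactions: InteractionTable,
    disease_interactions: InteractionTable,
    semantic: SimilarityMatrix | None = None,
    alpha: float = 0.5,
    variance_threshold: float = 0.80,
    top_k: int = 200,
    group_size: int = 50,
) -> PipelineContext:
    """Build similarity matrices and PCA models from the three data sources.

    ``semantic`` is the precomputed disease semantic-similarity matrix; when
    given, the disease similarity is SD = α·semantic + (1−α)·functional,
    otherwise the functional similarity is used alone.
    """
    mirna_corpus = build_corpus(mirna_interactions)
    disease_corpus = build_corpus(disease_interactions)
    SM = functional_similarity_matrix(mirna_corpus, assoc.mirnas)
    SD2 = functional_similarity_matrix(disease_corpus, assoc.diseases)
    if semantic is not None:
        SD1 = subset_similarity(semantic, assoc.diseases)
        SD = integrate_similarity(SD1, SD2, alpha)
    else:
        SD = SD2
    pca_models = fit_block_pca(SM, SD, variance_threshold)
    return PipelineContext(
        assoc=assoc,
        SM=SM,
        SD=SD,
        pca_models=pca_models,
        mirna_corpus=mirna_corpus,
        disease_corpus=disease_corpus,
        alpha=alpha,
        variance_threshold=variance_threshold,
        top_k=top_k,
        group_size=group_size,
    )


def make_training_set(
    ctx: PipelineContext,
    seed: int,
    neg_ratio: float = 1.0,
    exclude_disease: int | None = None,
) -> TrainingSet:
    return build_training_set(
        ctx.assoc, ctx.SM, ctx.SD, ctx.pca_models,
        ctx.mirna_corpus, ctx.disease_corpus,
        seed=seed, neg_ratio=neg_ratio,
        top_k=ctx.top_k, group_size=ctx.group_size,
        exclude_disease=exclude_disease,
    )


def cross_validate(
    ctx: PipelineContext,
    seed: int,
    spec: EnsembleSpec | None = None,
    folds: int = 5,
    repeats: int = 1,
    neg_ratio: float = 1.0,
    threshold: float = 0.5,
) -> CvReport:
    """Sample negatives, assemble features and run stratified K-fold CV."""
    train = make_training_set(ctx, seed=seed, neg_ratio=neg_ratio)
    return run_cross_validation(
        train, spec, folds=folds, repeats=repeats, seed=seed, threshold=threshold
    )
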