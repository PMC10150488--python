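"""Per-pair feature construction: PCA-reduced similarity rows + 17
structural descriptors.

Each candidate (miRNA i, disease j) is encoded as

    PCA(SM(i,:)) ∥ PCA(SD(j,:)) ∥ f(1..17)

where the two PCA models are fitted separately on the m miRNA similarity rows
and the d disease similarity rows, keeping the smallest number of components
whose cumulative explained variance reaches the threshold (default 80%), and
f is the structural feature vector:

    f1  miRNA target-gene count          f9   disease gene count
    f2  miRNA gene density               f10  disease gene density
    f3  mean of SM(i,:) (self excluded)  f11  mean of SD(j,:)
    f4  variance of SM(i,:)              f12  variance of SD(j,:)
    f5-f8  mean similarity of the top-ranked neighbour groups
           (ranks 1-50, 51-100, 101-150, 151-200 by default)
    f13-f16  the disease analogues of f5-f8
    f17 shared genes between the miRNA's targets and the disease's genes

Density is the entity's gene count over the number of distinct genes in its
interaction corpus.  When fewer than ``top_k`` comparators exist the
available K = min(top_k, n−1) neighbours are split into the same number of
contiguous groups (ceil(K/4) each, last possibly short; empty group → 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .containers import SimilarityMatrix
from .similarity import InteractionCorpus

N_STRUCTURAL = 17


@dataclass
class PcaModel:
    """Fitted PCA block: loadings, centering and retained variance."""

    block: str
    components: np.ndarray  # (n_components, n_features)
    mean: np.ndarray
    n_components: int
    explained_fraction: float
    explained_ratios: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


@dataclass
class FeatureTable:
    """Feature matrix for a list of (miRNA index, disease index) pairs."""

    pairs: list[tuple[int, int]]
    values: np.ndarray
    labels: np.ndarray | None
    block_bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return len(self.pairs)


def _entity_structural(
    row: np.ndarray,
    self_idx: int,
    gene_count: int,
    corpus_genes: int,
    top_k: int,
    group_size: int,
) -> np.ndarray:
    """The 8 per-entity structural features (count, density, row moments,
    top-neighbour group means)."""
    others = np.delete(row, self_idx)
    n_groups = max(1, math.ceil(top_k / group_size))
    out = np.zeros(4 + n_groups)
    out[0] = gene_count
    out[1] = gene_count / corpus_genes if corpus_genes else 0.0
    if others.size:
        out[2] = others.mean()
        out[3] = others.var()  # population variance
        # descending similarity, ties broken by ascending entity index
        order = np.lexsort((np.arange(others.size), -others))
        k = min(top_k, others.size)
        ranked = others[order[:k]]
        gs = group_size if others.size >= top_k else math.ceil(k / n_groups)
        for g in range(n_groups):
            chunk = ranked[g * gs : (g + 1) * gs]
            out[4 + g] = chunk.mean() if chunk.size else 0.0
    return out


def structural_features(
    i: int,
    j: int,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    mirna_corpus: InteractionCorpus,
    disease_corpus: InteractionCorpus,
    top_k: int = 200,
    group_size: int = 50,
) -> np.ndarray:
    """The 17-component structural descriptor of pair (miRNA i, disease j)."""
    mi_set = mirna_corpus.sets.get(SM.registry.ids[i], frozenset())
    di_set = disease_corpus.sets.get(SD.registry.ids[j], frozenset())
    f_mi = _entity_structural(
        SM.values[i], i, len(mi_set), mirna_corpus.n_genes, top_k, group_size
    )
    f_di = _entity_structural(
        SD.values[j], j, len(di_set), disease_corpus.n_genes, top_k, group_size
    )
    return np.concatenate([f_mi, f_di, [float(len(mi_set & di_set))]])


def encode_raw_samples(
    pairs: Sequence[tuple[int, int]], SM: SimilarityMatrix, SD: SimilarityMatrix
) -> np.ndarray:
    """Raw sample row for pair (i, j): SM(i,:) ∥ SD(j,:), width m + d."""
    m, d = SM.values.shape[0], SD.values.shape[0]
    idx = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if idx.size and (
        idx[:, 0].min() < 0 or idx[:, 0].max() >= m or idx[:, 1].min() < 0 or idx[:, 1].max() >= d
    ):
        raise IndexError("pair index out of range")
    return np.hstack([SM.values[idx[:, 0]], SD.values[idx[:, 1]]])


def _fit_pca(rows: np.ndarray, threshold: float, block: str) -> PcaModel:
    pca = PCA(svd_solver="full")
    pca.fit(rows)
    ratios = pca.explained_variance_ratio_
    if not np.isfinite(ratios).all() or ratios.sum() <= 0:
        # zero-variance block: a single (arbitrary) component carries nothing
        comps = np.zeros((1, rows.shape[1]))
        comps[0, 0] = 1.0
        return PcaModel(block, comps, rows.mean(axis=0), 1, 1.0, np.array([1.0]))
    cum = np.cumsum(ratios)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(ratios))
    comps = pca.components_[:k].copy()
    # fix the sign ambiguity: largest-magnitude loading of each component > 0
    for c in comps:
        peak = np.argmax(np.abs(c))
        if c[peak] < 0:
            c *= -1.0
    return PcaModel(block, comps, pca.mean_, k, float(cum[k - 1]), ratios[:k].copy())


def fit_block_pca(
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    variance_threshold: float = 0.80,
) -> tuple[PcaModel, PcaModel]:
    """Fit one PCA per similarity block on its unique rows (m and d rows)."""
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError(f"variance threshold must be in (0, 1], got {variance_threshold}")
    return (
        _fit_pca(SM.values, variance_threshold, "miRNA"),
        _fit_pca(SD.values, variance_threshold, "disease"),
    )


def feature_width(mirna_components: int, disease_components: int) -> int:
    """Final per-pair feature width: both PCA blocks plus the 17 structural."""
    return mirna_components + disease_components + N_STRUCTURAL


def assemble_feature_table(
    pairs: Sequence[tuple[int, int]],
    labels: Sequence[int] | None,
    SM: SimilarityMatrix,
    SD: SimilarityMatrix,
    pca_models: tuple[PcaModel, PcaModel],
    mirna_corpus: InteractionCorpus,
    disease_corpus: InteractionCorpus,
    top_k: int = 200,
    group_size: int = 50,
) -> FeatureTable:
    """Encode pairs as PCA blocks + structural features.

    The expensive per-entity parts of the structural vector are computed once
    per miRNA / disease and reused across pairs; the result is identical to
    calling :func:`structural_features` per pair.
    """
    pairs = [tuple(p) for p in pairs]
    if labels is not None and len(labels) != len(pairs):
        raise ValueError("labels length does not match pair count")
    pca_mi, pca_di = pca_models
    km, kd = pca_mi.n_components, pca_di.n_components
    width = feature_width(km, kd)
    bounds = ((0, km), (km, km + kd), (km + kd, width))
    if not pairs:
        return FeatureTable([], np.zeros((0, width)), None, bounds)

    mi_idx = np.array([p[0] for p in pairs])
    di_idx = np.array([p[1] for p in pairs])
    mi_sets = {
        i: mirna_corpus.sets.get(SM.registry.ids[i], frozenset()) for i in set(mi_idx)
    }
    di_sets = {
        j: disease_corpus.sets.get(SD.registry.ids[j], frozenset()) for j in set(di_idx)
    }
    mi_struct = {
        i: _entity_structural(
            SM.values[i], i, len(mi_sets[i]), mirna_corpus.n_genes, top_k, group_size
        )
        for i in mi_sets
    }
    di_struct = {
        j: _entity_structural(
            SD.values[j], j, len(di_sets[j]), disease_corpus.n_genes, top_k, group_size
        )
        for j in di_sets
    }
    structural = np.array(
        [
            np.concatenate(
                [mi_struct[i], di_struct[j], [float(len(mi_sets[i] & di_sets[j]))]]
            )
            for i, j in pairs
        ]
    )
    values = np.hstack(
        [
            pca_mi.transform(SM.values[mi_idx]),
            pca_di.transform(SD.values[di_idx]),
            structural,
        ]
    )
    lab = None if labels is None else np.asarray(labels, dtype=int)
    return FeatureTable(pairs=pairs, values=values, labels=lab, block_bounds=bounds)
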