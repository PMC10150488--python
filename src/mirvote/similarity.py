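"""Entropy-based functional similarity over shared target genes.

The similarity between two entities (two miRNAs, or two diseases) is the
normalized mutual information of their annotated gene sets:

    sim(A, B) = 2 * H(T_A ∩ T_B) / (H(T_A) + H(T_B))

where H is the information entropy of a gene set under the corpus-wide gene
frequencies: H(T) = Σ_{t∈T} −p(t)·log2 p(t) with p(t) = n(t)/N, n(t) the
number of entities annotated with gene t and N the total number of
(entity, gene) interactions.  Genes shared by few entities carry high
information, so overlap in rare genes counts for more than overlap in
ubiquitous ones.

Conventions for the degenerate cases the formula leaves open:

* an entity with an empty gene set has H = 0 and similarity 0 to everything,
  including itself — it carries no evidence, so it gets no fake self-signal;
* when H(T_A) + H(T_B) = 0 the similarity is defined as 0;
* the intersection entropy uses the same global p(·) as the marginals.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .containers import EntityRegistry, InteractionTable, SimilarityMatrix


@dataclass
class InteractionCorpus:
    """Gene-annotation sets plus the global frequency table they induce."""

    sets: Mapping[str, frozenset[str]]
    N: int
    freq: Mapping[str, int]
    p: Mapping[str, float]
    #: cached per-gene entropy contribution −p·log2 p
    info: Mapping[str, float] = field(repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.freq)


def build_corpus(interactions: InteractionTable) -> InteractionCorpus:
    """Count each deduplicated (entity, gene) pair once and derive p = n/N."""
    N = interactions.n_interactions
    if N == 0:
        raise ValueError("empty interaction corpus")
    sets: dict[str, set[str]] = {e: set() for e in interactions.entities.ids}
    freq: Counter[str] = Counter()
    for entity, gene in interactions.pairs:
        sets[entity].add(gene)
        freq[gene] += 1
    p = {g: n / N for g, n in freq.items()}
    info = {g: -pg * math.log2(pg) for g, pg in p.items()}
    return InteractionCorpus(
        sets={e: frozenset(s) for e, s in sets.items()},
        N=N,
        freq=dict(freq),
        p=p,
        info=info,
    )


def set_entropy(corpus: InteractionCorpus, genes: Iterable[str]) -> float:
    """Information entropy of a gene set, in bits.

    Genes absent from the corpus have no defined frequency and are ignored
    with a warning; an empty set has entropy 0.
    """
    total = 0.0
    unknown = 0
    for g in set(genes):
        w = corpus.info.get(g)
        if w is None:
            unknown += 1
        else:
            total += w
    if unknown:
        warnings.warn(f"{unknown} gene(s) absent from the corpus were ignored")
    return total


def nmi_similarity(
    corpus: InteractionCorpus, set_a: frozenset[str], set_b: frozenset[str]
) -> float:
    h_a = set_entropy(corpus, set_a)
    h_b = set_entropy(corpus, set_b)
    denom = h_a + h_b
    if denom <= 0.0:
        return 0.0
    return min(1.0, 2.0 * set_entropy(corpus, set_a & set_b) / denom)


def functional_similarity_matrix(
    corpus: InteractionCorpus, registry: EntityRegistry
) -> SimilarityMatrix:
    """All-pairs NMI similarity for the registry's entities.

    Entities missing from the corpus (annotated nowhere) get empty sets and
    hence all-zero rows, diagonal included.  Implemented with a weighted
    membership matrix so the result is exactly symmetric: with M the binary
    entity-by-gene matrix and w the per-gene information weights,
    H_i = (M w)_i and H(T_i ∩ T_j) = (M diag(w) Mᵀ)_ij.
    """
    genes = sorted(corpus.freq)
    gene_idx = {g: k for k, g in enumerate(genes)}
    n = len(registry)
    M = np.zeros((n, len(genes)))
    for i, entity in enumerate(registry.ids):
        for g in corpus.sets.get(entity, ()):  # missing entity -> empty set
            M[i, gene_idx[g]] = 1.0
    w = np.array([corpus.info[g] for g in genes])
    H = M @ w
    inter = (M * w) @ M.T
    denom = H[:, None] + H[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0.0, 2.0 * inter / np.where(denom > 0, denom, 1.0), 0.0)
    values = np.clip(values, 0.0, 1.0)
    # the diagonal is exactly 2H/(H+H): pin it against BLAS rounding
    np.fill_diagonal(values, np.where(H > 0.0, 1.0, 0.0))
    return SimilarityMatrix(registry=registry, values=values)


def subset_similarity(
    sim: SimilarityMatrix, registry: EntityRegistry
) -> SimilarityMatrix:
    """Restrict a similarity matrix to a (sub)registry's entities, in the
    target registry's order."""
    missing = [e for e in registry.ids if e not in sim.registry]
    if missing:
        raise KeyError(f"entities absent from similarity matrix: {missing[:5]}")
    idx = np.array([sim.registry.index[e] for e in registry.ids])
    return SimilarityMatrix(registry=registry, values=sim.values[np.ix_(idx, idx)])


def integrate_similarity(
    sd1: SimilarityMatrix, sd2: SimilarityMatrix, alpha: float = 0.5
) -> SimilarityMatrix:
    """Convex blend α·SD1 + (1−α)·SD2 of semantic and functional similarity."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if sd1.registry.ids != sd2.registry.ids:
        raise ValueError("similarity matrices have mismatched registries")
    return SimilarityMatrix(
        registry=sd1.registry,
        values=alpha * sd1.values + (1.0 - alpha) * sd2.values,
    )
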