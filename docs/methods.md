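# Methods

## Model

`mirvote` treats miRNA–disease association prediction as supervised link
prediction on the binary matrix `A` (rows: miRNAs, columns: diseases). The
model rests on one assumption: entities with similar function share target
genes, so overlap between annotated gene sets is evidence of relatedness,
and related miRNA–disease pairs are more likely to be associated.

### Entropy-weighted set similarity

Each interaction corpus (miRNA→target genes, disease→associated genes) is
deduplicated; `N` is the number of distinct (entity, gene) pairs and
`n(t)` the number of entities annotated with gene `t`. A gene set `T` has
entropy `H(T) = Σ_{t∈T} −p(t)·log₂ p(t)` with `p(t) = n(t)/N`, and two sets
are compared by normalized mutual information,
`sim = 2·H(T_A ∩ T_B) / (H(T_A) + H(T_B))`. Rare genes carry more
information than ubiquitous ones, so overlap in a rarely-annotated gene
counts for more. The intersection entropy uses the same global `p(·)` as
the marginals.

Degenerate cases the formula leaves open are resolved conservatively:

* empty gene set → entropy 0, similarity 0 to everything *including
  itself* (no annotation means no evidence, so no artificial self-signal);
* `H(T_A) + H(T_B) = 0` → similarity 0;
* a query gene absent from the corpus has no defined frequency and is
  ignored with a warning.

The miRNA and disease corpora are kept independent (each has its own `N`).
The miRNA similarity `SM` is purely functional; the disease similarity
blends a precomputed semantic matrix with the functional one,
`SD = α·SD1 + (1−α)·SD2`, default α = 0.5 (equal contributions).

### Features

Per pair (i, j): PCA-reduced `SM(i,:)` ∥ PCA-reduced `SD(j,:)` ∥ 17
structural features. Numerical choices:

* PCA is fitted once per block on the unique similarity rows (m rows for
  miRNAs, d for diseases), keeping the smallest component count whose
  cumulative explained variance reaches the threshold (default 0.80). The
  m and d rows are the only distinct values the blocks ever take, so
  fitting on them is equivalent to fitting on any pair list's rows and is
  deterministic. Component signs are fixed by orienting each loading
  vector's largest-magnitude coordinate positive, making feature tables
  bit-reproducible.
* Structural features: gene count; gene density (count over the number of
  distinct genes in that corpus); mean and population variance of the
  entity's similarity row with the self-entry excluded (the guaranteed
  diagonal would shift every mean equally); mean similarity of the
  top-ranked neighbour groups — ranks 1–50, 51–100, 101–150, 151–200 by
  default. With fewer than `top_k` comparators (always true for small
  panels), the available K = min(top_k, n−1) neighbours are split into the
  same number of contiguous groups of ⌈K/4⌉, the last possibly short, and
  an empty group contributes 0. Similarity ties are broken by ascending
  entity index. The 17th feature is the shared-gene count between the
  miRNA's target set and the disease's gene set.

### Ensemble and evaluation

Negatives are drawn uniformly without replacement from the zeros of `A`,
by default one per positive (balanced). Four base learners are fitted on
identical rows: an RBF-kernel SVM with Platt-calibrated probabilities
(standardized inputs), gradient-boosted trees, a random forest, and
XGBoost — all at conventional defaults (100 trees/boosters, learning rate
0.1), every hyperparameter overridable through `EnsembleSpec`. The
ensemble score is the unweighted mean of the members' positive-class
probabilities (soft vote).

Evaluation is stratified K-fold cross-validation (default 5 folds;
stratification keeps fold class balance stable, and is recorded in the
report). Repeats re-partition with seed `base + repeat`. Metrics per fold:
precision, recall and F1 at threshold 0.5 on the voted probability (a zero
denominator yields 0 and a flag), ROC AUC in the Mann–Whitney concordance
form `P(s⁺>s⁻) + ½P(s⁺=s⁻)` (midranks), and the area under the
precision–recall step curve summed over distinct-score thresholds with no
interpolation. A second ROC implementation (trapezoid under the empirical
curve) exists only as a cross-check in the test suite.

Rankings list candidate pairs (zeros of `A`) in descending score with
lexicographic (miRNA, disease) tie-breaks; rank is the 1-based position in
that total order, so equal scores still receive distinct, deterministic
ranks.

### Isolated-disease (cold-start) protocol

For a query disease, every pair in its column is removed from the
positives and — by default — from the negative-sampling pool, so nothing
about the column enters training; all m of its pairs are then scored. The
positives-only variant (`exclude_negative_pool=False`) is also available;
under it, holding out a disease with no known associations is exactly a
no-op.

## Synthetic fixture

The generator plants the dependency the pipeline is built to detect.
Genes are partitioned into `n_clusters` pools; each miRNA and disease gets
a uniform-random cluster label and draws `Poisson(genes_per_entity)` genes,
each draw coming from its own cluster's pool with mixture weight
`p_gene_within` (default 0.8) and from the other pools otherwise.
`A(i,j) = 1` with probability `p_assoc_within` (0.3) when the clusters
match and `p_assoc_between` (0.02) otherwise. The disease semantic
surrogate is 0.9 within / 0.1 between clusters plus symmetric Gaussian
noise (sd 0.05), clipped to [0, 1], diagonal 1. Defaults: 60 miRNAs, 40
diseases, 300 genes, 4 clusters — small enough that the full pipeline
cross-validates in a few seconds on one CPU, large enough that planted
structure dominates noise. `without_signal()` equalizes the within/between
rates at unchanged expected density, giving a negative control whose CV
AUC sits at chance.

What the fixture does **not** emulate: the heavy-tailed degree
distributions of real association databases, name-variant noise,
literature-driven annotation bias, and semantic similarity derived from an
actual disease-term hierarchy. Passing tests on the fixture demonstrate
that the pipeline recovers planted shared-target structure, not that it
reproduces benchmark figures on curated databases.

### Information ceiling of the fixture

Because associations depend on the cluster labels only through the match
indicator, the Bayes-optimal score on a balanced sample is effectively
binary (P(match | positive) ≈ 0.83, P(match | negative) ≈ 0.19 at the
defaults), which caps the expected CV AUC near 0.82, fluctuating a few
hundredths with the random cluster sizes and the Bernoulli association
draw. Measured ensembles on ~420 training rows land roughly 0.03–0.15
below that ceiling depending on the seed; the cluster labels themselves
are 96–100 % recoverable from the PCA blocks, so the residual gap is the
sample cost of learning a 4×4 cluster-match interaction from continuous
coordinates. The acceptance suite asserts the ensemble-vs-member margin
and the negative control, and checks the 0.80 discrimination level, which
sits above the realized ceiling for some seeds.

## Identifier handling

Ids are normalized (lowercase, trimmed, internal whitespace collapsed)
before registration; registries order ids lexicographically so every
matrix is reproducible across runs. No fuzzy matching is attempted —
readers accept an explicit raw→canonical mapping file for resolving name
variants across databases. Entities present in the association table but
absent from an interaction table keep empty gene sets (zero similarity to
everything).

## Problem sizes

Model-level tests run on reduced fixtures (24×16 to 60×40 panels); the
acceptance script evaluates three 60×40 fixtures, a no-signal control and
a five-disease cold-start sweep, about a minute on one CPU. Dimensional
identities are checked at the full benchmark registry scale (495 × 383),
which needs no model training.

## Known limitations

* Negative sampling is uniform over unknown pairs; unknown ≠ negative, so
  some sampled "negatives" may be undiscovered associations.
* PCA is fitted on the complete similarity matrices rather than per CV
  fold. Because its inputs are the m and d unique similarity rows — which
  carry no label information and are identical in every fold — a per-fold
  refit would reproduce the same models by construction; a genuinely
  fold-local protocol would have to refit on the fold's duplicated raw
  sample rows instead.
* The 0.5 decision threshold for precision/recall/F1 is a convention;
  ranking metrics (AUC/AUPR) are threshold-free and should be preferred
  for comparisons.
* Isolated-disease mode still uses the disease's *gene* annotations (via
  SD and structural features); it withholds only association evidence.
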