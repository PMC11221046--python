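# Methods

This note records the model, the numerical conventions, the defaults and
the design choices behind `specmod`, in the spirit of a package vignette.

## Model and assumptions

The pipeline assumes the expression matrix is already normalized and
batch-corrected; it performs no unit conversion. Rows containing
non-finite values are dropped with a warning (strict mode errors); they
are never imputed. Gene vectors are scaled to unit Euclidean norm, so
all downstream similarity is driven by expression *shape*, not
amplitude. For unit vectors the squared distance and the inner product
are interchangeable (‖g_i − g_j‖² = 2(1 − g_i·g_j)); for roughly centered
expression rows the kernel is therefore a monotone transform of the
gene–gene correlation.

The Gaussian-kernel bandwidth γ² is the variance of the pairwise squared
distances — each unordered pair counted once, self-distances excluded
(they are identically zero and would deflate the estimate). Population
variance is the default; the sample (n−1) estimator and a manual
`--bandwidth` override are available. A degenerate input in which all
pairwise distances coincide has zero variance and is rejected with
advice to supply a bandwidth manually.

The topological overlap enhancement uses the convention of the WGCNA/TOM
literature: the shared-neighbour sum l_ij runs over third nodes
u ∉ {i, j}, and the connectivity k_i excludes the diagonal. Under this
convention a_ij ∈ [0, 1] is guaranteed; including u ∈ {i, j} can push
values above 1. The adjacency is dense by construction (the kernel is
strictly positive); a warning is emitted above 20 000 genes (~3.2 GB).

## Spectral embedding

Eigenpairs of the random-walk operator D⁻¹A are computed through the
symmetric form D^(−1/2)AD^(−1/2): identical eigenvalues, eigenvectors
mapped back by D^(−1/2). Networks of at most 500 nodes use a dense full
decomposition; larger ones use ARPACK (`eigsh`, algebraically largest).
The number of retained eigenpairs defaults to min(m, max(2·k_max + 2,
50)) with k_max = 40, enough to build a 2k-column embedding for any
candidate the search can return.

Eigenvector post-processing: each retained column y is centered by
subtracting (1ᵀDy)/m from every entry, scaled so that yᵀDy = 1, and
sign-fixed (largest-magnitude entry positive) for reproducibility; the
leading trivial column is dropped. The printed /m centering is the
default; a degree-weighted alternative ((1ᵀDy)/(1ᵀD1), which exactly
annihilates the trivial constant vector) is available via
`centering="weighted_mean"`. Numerically degenerate columns (D-norm
below 1e-12 after centering) are left unscaled rather than divided by
zero.

The three eigengap objectives are evaluated on the descending spectrum
over 1-based indices i = 2 … p−2 (further capped at k_max). The additive
gap is taken as λ_i − λ_{i+1}, the magnitude of the drop — under a
descending sort the opposite orientation is uniformly negative and its
argmax carries no information, and only this orientation makes the
relative gap behave as a cluster-count detector. On disconnected
networks the repeated trivial eigenvalue makes 1 − λ vanish; the ratio
denominators are floored at 1e-12 with a logged warning, which makes the
relative gap spike exactly at the component count (verified for 2–5
disconnected cliques).

## Clustering and the choice of k

For each candidate k, the embedding is the first 2k retained eigenvector
columns with rows scaled to unit norm. kmeans uses Lloyd iterations with
kmeans++ seeding, 50 restarts and 300 iterations by default — restart
and iteration caps are exposed in the configuration for users who want
the much larger safety bounds sometimes quoted for R's kmeans; they are
safety margins, not algorithmic content. Labels are canonically
renumbered in order of first occurrence so that repeated runs are
byte-identical. Duplicate candidate values of k are clustered once and
shared.

Cluster conductance is cut(C, C̄)/vol(C) with degrees taken from the
adjacency; a zero diagonal guarantees values in [0, 1]. Each candidate's
minimum-conductance cluster (ties to the smallest label) is its test
cluster. The candidate whose test cluster maximizes the summed
−log₁₀ p of its retained enrichment records wins; quality ties respect
the precedence additive > relative > second-order gap. If no test
cluster has any enriched term the candidate with the
smallest test-cluster conductance is used, with a warning.

The validation quality sums **over-representation records only** by
default (`quality_directions="over"`). This is a deliberate choice: an
under-representation record measures what a cluster *excludes*, and in a
partition a coarse cluster's complement necessarily excludes whole
modules, so including under-representation records systematically
inflates the quality of merged clusterings. On planted-module data this
bias was strong enough to flip the selected k from the true value to a
two-cluster merge. The enrichment *report* itself still contains all six
queries (over/under × BP/CC/MF).

## Enrichment

The test is a plain per-term hypergeometric over/under tail
(`scipy.stats.hypergeom`), with the whole gene universe of the dataset
as background. No GO-DAG conditioning and no annotation propagation is
performed: annotations are used exactly as given, and terms with fewer
than two genes are tested like any other. p-values are raw by default —
an optional Benjamini–Hochberg helper exists but is off, since the
module-quality metrics are defined on raw p-values. The significance
cutoff for retaining a record defaults to p ≤ 0.05. Odds-ratio
conventions: x = 0 → 0; zero denominator with x > 0 → +inf (serialized
as `inf`).

Annotation input is a 2/3-column table (gene, term[, namespace];
namespace defaults to BP when absent) or GAF 2.x, in which NOT-qualified
lines are skipped and both the object id and symbol are matched against
the universe.

## Semi-labeling and classification

Enrichment records of all clusters are pooled and the ⌈top_fraction ·
total⌉ records with the smallest p-values are selected (default 0.10;
boundary ties broken by (cluster, term, direction) lexical order).
Pooling across clusters — rather than per cluster — is what allows a
weakly enriched cluster to contribute nothing and be dropped. A gene is
remarkable only through selected records *of its own cluster*; being
annotated to another cluster's selected term does not count. Both test
directions participate in the pool by default
(`semilabel_directions`); in practice the strongly over-represented
signature terms dominate the selection.

The kNN neighbour grid is the inclusive integer range [20, 20 + 2k] when
2k ≤ 30 and [20, 30] otherwise, capped below the training-set size
(re-floored at 1 for tiny training sets). The count is chosen by
stratified 5-fold cross-validated accuracy (folds seeded; fold count
reduced when a class is smaller than 5; single-member classes skip CV);
ties prefer the smaller count. Logistic regression is one-vs-rest with
fixed L2 strength 1.0. Remarkable genes always keep their training
labels. The refinement summary reports %UNR (share of unremarkable
genes) and %CH (share of unremarkable genes whose final label differs
from their initial cluster's mapped label; genes from a dropped cluster
count as changed; with no unremarkable genes %CH is reported as 0 with a
flag).

## Evaluation metrics

Module quality q_j = −(Σ log₁₀ p_{i,j})/n_j over the n_j retained terms
of module j; framework quality Q_f is the mean of q_j over modules with
n_j > 0 (empty modules excluded with a logged count; the pooled mean of
−log₁₀ p over all records is also emitted). The *prominent* module is
the one containing the globally most significant term (ties to the
smaller module id); its top-10 p-values and top-100 unique term ids
(a term reported in both directions counts once, smallest p kept)
support cross-framework comparison via term-set overlap.

## Synthetic data

`generate_expression` plants equicorrelated modules with a latent-factor
model: x = √ρ·z_module + √(1−ρ)·ε, all draws standard normal, scaled by
`noise_sd`. This is equivalent to (and O(m·n) cheaper than) sampling
from the corresponding block covariance via a Cholesky factor. The
latent module profiles are orthogonalised in-sample (centered QR with a
deterministic orientation): with few samples, independent Gaussian
profiles carry spurious pairwise correlations of order 1/√n — up to
±0.3 at n = 30 — which would genuinely couple the planted modules
instead of leaving them uncorrelated as the design intends. This
requires fewer modules than samples. Within-module sample correlation
concentrates around `within_corr`; between-module correlation is pure
gene-level noise.

`generate_annotation` gives each module `n_terms_per_module` signature
terms, each covering `term_coverage` of the module's genes plus
background genes at rate `background_annotation_rate` (so that foreign
clusters still overlap the term and under-representation queries are
exercised), and `background_terms` terms annotated uniformly at random.
Namespaces rotate BP/CC/MF so all six queries occur. Degrading a module
replaces its signature terms with same-sized uniform draws, destroying
its enrichment while keeping the term count — the mechanism used to
demonstrate cluster elimination during refinement.

Defaults — four modules of 100 genes, 30 samples, ρ = 0.8, coverage 0.6,
12 signature terms per module, 100 background terms of size 10–30,
3 % background annotation — describe a strongly modular, well-annotated
dataset. Real data differ in ways the generator does not emulate: no
count/microarray noise distributions or library-size effects, no
hierarchically nested or overlapping modules, no annotation bias toward
well-studied genes, no GO DAG structure. Passing the recovery tests
therefore demonstrates the pipeline's correctness and internal
consistency under its own assumptions, not performance on any real
tissue.

## Problem sizes and determinism

The test suite runs the full pipeline on 4 × 100-gene designs (the
default study condition) and 4 × 40-gene variants for fast unit tests;
networks in oracle tests stay below 50 nodes so that O(m³) brute-force
recomputation is exact and cheap. All randomness — generation, kmeans
restarts, CV folds — is derived from explicit seeds, and identical
configuration plus seed reproduces every output file byte-for-byte.

## Known limitations

- The eigengap heuristics propose at most three candidate counts; if
  none of them is correct the GO validation cannot recover it. The
  configuration accepts a user-forced k for exactly this case.
- The conductance-based test cluster summarises a whole clustering by
  its single best cluster; a candidate with one excellent and many poor
  clusters can win.
- The hypergeometric test treats GO terms as independent gene sets; in
  real annotations nested terms produce correlated records, and the
  pooled top-fraction selection can be dominated by one deep branch.
- Dense m × m matrices bound the practical network size (memory grows
  quadratically); above ~20 000 genes a warning is issued.
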