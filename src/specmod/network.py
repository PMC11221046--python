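"""Co-expression network construction.

The network is built in three steps: each gene's expression vector is
scaled to unit Euclidean norm, pairwise similarities are computed with a
Gaussian kernel whose bandwidth is estimated from the data, and the
similarity matrix is enhanced with second-order neighbourhood information
via the topological overlap measure (TOM).  The result is a dense,
symmetric, zero-diagonal adjacency matrix with entries in [0, 1].

Unlike soft-thresholding pipelines, no scale-free topology criterion is
involved: the kernel bandwidth is a simple statistic (the variance of the
pairwise squared distances between unit-normalised gene vectors).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: warn when building a dense m x m network above this many genes
DENSE_WARN_GENES = 20_000


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with row/column identifiers.

    Values are assumed to be normalized and batch-corrected upstream;
    no unit conversion is performed here.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if not self.sample_ids:
            self.sample_ids = [f"s{j + 1}" for j in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} columns")
        if m < 3 or n < 2:
            raise ValueError(f"need at least 3 genes and 2 samples, got {m} x {n}")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene identifiers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def drop_nonfinite(self, policy: str = "drop") -> "ExpressionMatrix":
        """Handle rows with non-finite entries.

        ``policy="drop"`` removes them with a warning; ``"error"`` raises.
        Missing values are never imputed.
        """
        bad = ~np.isfinite(self.values).all(axis=1)
        if not bad.any():
            return self
        offenders = [g for g, b in zip(self.gene_ids, bad) if b]
        if policy == "error":
            raise ValueError(f"non-finite expression values in genes: {offenders[:10]}")
        logger.warning("dropping %d genes with non-finite values", len(offenders))
        keep = ~bad
        return ExpressionMatrix(
            [g for g, k in zip(self.gene_ids, keep) if k],
            self.values[keep],
            list(self.sample_ids),
        )


@dataclass
class NormalizedExpression:
    """Expression matrix whose rows are unit vectors."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class SimilarityMatrix:
    """Symmetric Gaussian-kernel similarity matrix with unit diagonal."""

    values: np.ndarray
    bandwidth_sq: float


@dataclass
class AdjacencyMatrix:
    """TOM-enhanced adjacency: symmetric, entries in [0, 1], zero diagonal."""

    values: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=1)


def normalize_genes(ge: ExpressionMatrix) -> NormalizedExpression:
    """Scale each gene's expression vector to unit Euclidean norm.

    Raises
    ------
    ValueError
        If any gene has an all-zero (zero-norm) expression vector, naming
        the offending gene.
    """
    norms = np.linalg.norm(ge.values, axis=1)
    zero = norms <= 0.0
    if zero.any():
        offenders = [g for g, z in zip(ge.gene_ids, zero) if z]
        raise ValueError(
            f"cannot normalize zero-norm expression rows for genes: {offenders[:10]}"
        )
    return NormalizedExpression(list(ge.gene_ids), ge.values / norms[:, None])


def pairwise_sq_distances(g: NormalizedExpression) -> np.ndarray:
    """Condensed vector of squared Euclidean distances, each unordered pair once."""
    from scipy.spatial.distance import pdist

    return pdist(g.values, metric="sqeuclidean")


def estimate_bandwidth(g: NormalizedExpression, estimator: str = "population") -> float:
    """Kernel bandwidth gamma^2: variance of the pairwise squared distances.

    Each unordered gene pair is counted once; self-distances (always zero)
    are excluded.  ``estimator`` selects the population (divide by the
    number of pairs, the default) or sample (n-1) variance.

    Raises
    ------
    ValueError
        If all pairwise distances are identical (zero variance); supply a
        bandwidth manually in that case.
    """
    if g.values.shape[0] < 3:
        raise ValueError("bandwidth estimation needs at least 3 genes")
    d2 = pairwise_sq_distances(g)
    if estimator == "population":
        var = float(np.var(d2))
    elif estimator == "sample":
        var = float(np.var(d2, ddof=1))
    else:
        raise ValueError(f"unknown variance estimator: {estimator!r}")
    if var <= 0.0:
        raise ValueError(
            "pairwise squared distances have zero variance; the Gaussian "
            "bandwidth cannot be estimated -- supply one manually "
            "(e.g. --bandwidth)"
        )
    return var


def gaussian_similarity(
    g: NormalizedExpression, bandwidth_sq: float
) -> SimilarityMatrix:
    """Gaussian-kernel similarity s_ij = exp(-||g_i - g_j||^2 / (2 gamma^2))."""
    if bandwidth_sq <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth_sq}")
    from scipy.spatial.distance import squareform

    d2 = squareform(pairwise_sq_distances(g))
    s = np.exp(-d2 / (2.0 * bandwidth_sq))
    # enforce exact symmetry / unit diagonal against fp round-off
    s = 0.5 * (s + s.T)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, float(bandwidth_sq))


def tom_enhance(s: SimilarityMatrix) -> AdjacencyMatrix:
    """Topological overlap enhancement of a similarity matrix.

    a_ij = (l_ij + s_ij) / (min(k_i, k_j) + 1 - s_ij) for i != j, where
    l_ij sums s_iu * s_uj over third nodes u (u not in {i, j}) and the
    connectivity k_i excludes the diagonal.  With this convention the
    output is guaranteed to stay in [0, 1]; the diagonal is set to zero.
    """
    sv = np.asarray(s.values, dtype=float)
    m = sv.shape[0]
    if sv.shape[0] != sv.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(sv, sv.T, atol=1e-12):
        raise ValueError("similarity matrix must be symmetric")
    if sv.min() < -1e-12 or sv.max() > 1 + 1e-12:
        raise ValueError("similarity entries must lie in [0, 1]")
    if m > DENSE_WARN_GENES:
        warnings.warn(
            f"building a dense {m} x {m} adjacency (~{8 * m * m / 1e9:.1f} GB)",
            ResourceWarning,
            stacklevel=2,
        )
    diag = np.diag(sv).copy()
    # shared-neighbour term: full product minus the u = i and u = j terms
    l = sv @ sv - diag[:, None] * sv - sv * diag[None, :]
    k = sv.sum(axis=1) - diag
    denom = np.minimum.outer(k, k) + 1.0 - sv
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten with 0 below
    a = (l + sv) / denom
    np.fill_diagonal(a, 0.0)
    a = 0.5 * (a + a.T)
    np.clip(a, 0.0, 1.0, out=a)
    return AdjacencyMatrix(a)


def build_network(
    ge: ExpressionMatrix,
    bandwidth_sq: float | None = None,
    variance_estimator: str = "population",
) -> tuple[NormalizedExpression, SimilarityMatrix, AdjacencyMatrix]:
    """Run the full construction: normalise, kernel similarity, TOM.

    ``bandwidth_sq`` overrides the estimated bandwidth when given.
    """
    g = normalize_genes(ge)
    if bandwidth_sq is None:
        bandwidth_sq = estimate_bandwidth(g, estimator=variance_estimator)
    s = gaussian_similarity(g, bandwidth_sq)
    return g, s, tom_enhance(s)
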