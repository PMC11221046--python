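"""Clustering of the spectral embedding and conductance-guided k selection.

For a candidate cluster count k, the embedding consists of the first 2k
processed eigenvector columns with rows scaled to unit length; kmeans on
its rows yields the clusters.  Each cluster's conductance (boundary weight
over cluster volume) measures how well separated it is; the minimum-
conductance cluster of each candidate clustering serves as that
candidate's *test cluster*, whose annotation enrichment ultimately decides
which k is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .network import AdjacencyMatrix
from .spectral import CandidateK, SpectralDecomposition

logger = logging.getLogger(__name__)

DEFAULT_N_INIT = 50
DEFAULT_MAX_ITER = 300
_EMPTY_CLUSTER_RETRIES = 5

#: tie precedence among gap methods, best first
METHOD_ORDER = ("ag", "rg", "sg")


@dataclass
class Embedding:
    """Row-normalised spectral coordinates: m rows, exactly 2k columns."""

    values: np.ndarray
    k: int
    gene_ids: list[str] | None = None


@dataclass
class Clustering:
    """A k-way partition of the genes with per-cluster conductance.

    Labels are integers in [1, k], relabelled canonically (cluster 1 is
    the cluster of the first gene, and so on by first occurrence).
    ``test_cluster`` is the minimum-conductance cluster's label.
    """

    labels: np.ndarray
    k: int
    method: str = "user"
    conductances: np.ndarray | None = None
    test_cluster: int | None = None
    gene_ids: list[str] | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def gene_sets(self) -> dict[int, list[str]]:
        if self.gene_ids is None:
            raise ValueError("clustering carries no gene identifiers")
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for g, lab in zip(self.gene_ids, self.labels):
            out[int(lab)].append(g)
        return out


def build_embedding(sd: SpectralDecomposition, k: int) -> Embedding:
    """First 2k retained eigenvector columns, rows scaled to unit norm."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ncols = sd.vectors.shape[1]
    if 2 * k > ncols:
        raise ValueError(
            f"embedding needs 2k = {2 * k} eigenvector columns but only "
            f"{ncols} were retained; increase n_eig"
        )
    y = sd.vectors[:, : 2 * k].copy()
    norms = np.linalg.norm(y, axis=1)
    zero = norms <= 1e-300
    if zero.any():
        idx = int(np.flatnonzero(zero)[0])
        name = sd.gene_ids[idx] if sd.gene_ids else f"gene index {idx}"
        raise ValueError(f"degenerate (all-zero) embedding row for {name}")
    return Embedding(y / norms[:, None], int(k), sd.gene_ids)


def _canonical_relabel(raw: np.ndarray) -> np.ndarray:
    """Relabel to 1..k in order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def run_kmeans(
    e: Embedding,
    k: int,
    seed: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Clustering:
    """Lloyd kmeans with kmeans++ restarts on the embedding rows.

    Labels are canonically relabelled for reproducibility.  An empty
    cluster (rare) triggers a re-run with a derived seed, up to a bound.
    """
    if k < 2:
        raise ValueError(f"kmeans needs k >= 2, got {k}")
    m = e.values.shape[0]
    if m <= k:
        raise ValueError(f"kmeans needs more points ({m}) than clusters ({k})")
    for attempt in range(_EMPTY_CLUSTER_RETRIES):
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            max_iter=max_iter,
            init="k-means++",
            algorithm="lloyd",
            random_state=(seed + 9973 * attempt) % (2**31),
        )
        raw = km.fit_predict(e.values)
        if len(np.unique(raw)) == k:
            return Clustering(_canonical_relabel(raw), int(k), gene_ids=e.gene_ids)
        logger.warning("kmeans produced an empty cluster; retrying (attempt %d)",
                       attempt + 1)
    raise RuntimeError(f"kmeans returned empty clusters in {_EMPTY_CLUSTER_RETRIES} attempts")


def conductance(a: AdjacencyMatrix, labels: np.ndarray, cluster: int) -> float:
    """Conductance of one cluster: boundary weight / cluster volume.

    conduct(C) = sum_{u in C, v not in C} a_uv / sum_{u in C} deg(u).
    Because the diagonal is zero the value always lies in [0, 1]; the
    whole node set has conductance 0 and a single node has conductance 1.
    """
    labels = np.asarray(labels)
    inside = labels == cluster
    if not inside.any():
        raise ValueError(f"cluster {cluster} not present in labels")
    deg = a.values.sum(axis=1)
    vol = deg[inside].sum()
    if vol <= 0:
        raise ValueError(f"cluster {cluster} has zero volume (isolated members)")
    cut = a.values[np.ix_(inside, ~inside)].sum()
    return float(cut / vol)


def all_conductances(a: AdjacencyMatrix, clustering: Clustering) -> np.ndarray:
    return np.array(
        [conductance(a, clustering.labels, c) for c in range(1, clustering.k + 1)]
    )


def with_conductances(a: AdjacencyMatrix, clustering: Clustering) -> Clustering:
    """Attach conductances and mark the minimum-conductance test cluster.

    Ties are broken by the smallest cluster label.
    """
    cond = all_conductances(a, clustering)
    return replace(
        clustering,
        conductances=cond,
        test_cluster=int(np.argmin(cond)) + 1,
    )


def select_test_clusters(
    a: AdjacencyMatrix,
    sd: SpectralDecomposition,
    ck: CandidateK,
    seed: int,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
) -> dict[str, Clustering]:
    """Cluster the embedding for each candidate k and mark test clusters.

    Candidates sharing the same k are computed once and shared (with the
    method tag adjusted), so duplicated candidates cost nothing extra.
    """
    by_k: dict[int, Clustering] = {}
    out: dict[str, Clustering] = {}
    for method, k in ck.as_dict().items():
        if k not in by_k:
            emb = build_embedding(sd, k)
            cl = run_kmeans(emb, k, seed, n_init=n_init, max_iter=max_iter)
            by_k[k] = with_conductances(a, cl)
        out[method] = replace(by_k[k], method=method)
    return out


def choose_k(
    test_results: dict[str, tuple[Clustering, float]],
) -> tuple[int, str, Clustering]:
    """Pick the candidate whose test cluster has the best enrichment quality.

    ``test_results`` maps method tag -> (clustering, quality), quality
    being the summed -log10 p over the test cluster's enriched terms.
    Quality ties respect the precedence ag > rg > sg.  If no test cluster
    has any enriched term, fall back to the candidate whose test cluster
    has the smallest conductance (same precedence on ties).
    """
    methods = [m for m in METHOD_ORDER if m in test_results]
    if not methods:
        methods = list(test_results)
    qualities = {m: test_results[m][1] for m in methods}
    if all(q <= 0.0 for q in qualities.values()):
        logger.warning(
            "no test cluster shows annotation enrichment; falling back to "
            "minimum-conductance selection"
        )
        def fallback(m: str) -> float:
            cl = test_results[m][0]
            return float(cl.conductances[cl.test_cluster - 1])
        best = min(methods, key=lambda m: (fallback(m), methods.index(m)))
    else:
        best = max(methods, key=lambda m: (qualities[m], -methods.index(m)))
    clustering = test_results[best][0]
    return clustering.k, best, clustering
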