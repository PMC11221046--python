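"""Spectral embedding of the co-expression network.

The clustering signal lives in the leading eigenpairs of the random-walk
operator D^-1 A (D the diagonal degree matrix).  Its eigenvalues lie in
[-1, 1]; eigenvalue 1 is trivial for each connected component, and the
number of well-separated leading eigenvalues indicates the number of
clusters.  Eigenpairs are computed through the symmetric conjugate
D^-1/2 A D^-1/2 (same eigenvalues; eigenvectors map back through
D^-1/2), dense for small networks and Lanczos (ARPACK) otherwise.

Retained eigenvectors are centered, scaled to unit D-norm and stripped of
the leading trivial constant vector before they are used as coordinates.
Three eigengap heuristics (additive, relative and second-order gap)
propose candidate cluster counts from the spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .network import AdjacencyMatrix

logger = logging.getLogger(__name__)

#: floor applied to (1 - lambda) denominators on (near-)disconnected networks
EIGENGAP_EPS = 1e-12

#: largest candidate cluster count searched by default
DEFAULT_K_MAX = 40

#: networks up to this many nodes use a dense full eigendecomposition
DENSE_THRESHOLD = 500


@dataclass
class SpectralDecomposition:
    """Leading eigenpairs of D^-1 A after eigenvector post-processing.

    ``eigenvalues`` holds the n_computed algebraically largest eigenvalues
    in descending order (the first is the trivial eigenvalue, ~1 for a
    connected network).  ``vectors`` is the m x (n_computed - 1) matrix of
    processed eigenvectors with the trivial leading column removed; column
    j corresponds to eigenvalue j+2 in 1-based counting.
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    degrees: np.ndarray
    gene_ids: list[str] | None = None

    @property
    def n_computed(self) -> int:
        return len(self.eigenvalues)


@dataclass
class CandidateK:
    """Candidate cluster counts from the three eigengap heuristics.

    ``gap_profiles`` maps method tag -> (index array, objective array) on
    the searched 1-based index range, kept for diagnostics.
    """

    k_ag: int
    k_rg: int
    k_sg: int
    gap_profiles: dict[str, tuple[np.ndarray, np.ndarray]]

    def as_dict(self) -> dict[str, int]:
        return {"ag": self.k_ag, "rg": self.k_rg, "sg": self.k_sg}


def default_n_eig(m: int, k_max: int = DEFAULT_K_MAX) -> int:
    """Number of eigenpairs to compute: enough for embeddings up to k_max."""
    return min(m, max(2 * k_max + 2, 50))


def _sign_fix(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude entry of each column positive (reproducibility)."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def decompose(
    a: AdjacencyMatrix,
    n_eig: int | None = None,
    dense_threshold: int = DENSE_THRESHOLD,
    centering: str = "printed_mean",
) -> SpectralDecomposition:
    """Eigendecompose the random-walk operator of an adjacency matrix.

    Parameters
    ----------
    a
        Symmetric zero-diagonal adjacency; every node must have positive
        degree.
    n_eig
        Number of algebraically largest eigenpairs to retain (default
        chosen to support embeddings up to ``DEFAULT_K_MAX`` clusters).
    dense_threshold
        Networks with at most this many nodes use a dense full
        eigendecomposition; larger ones use ARPACK.
    centering
        ``"printed_mean"`` subtracts (1^T D y) / m from each eigenvector
        entry; ``"weighted_mean"`` uses the degree-weighted mean
        (1^T D y) / (1^T D 1) instead.

    Each retained eigenvector is centered, scaled so that y^T D y = 1 and
    sign-fixed; the leading (trivial) column is dropped.
    """
    av = a.values
    m = av.shape[0]
    deg = av.sum(axis=1)
    if (deg <= 0).any():
        idx = int(np.argmin(deg))
        gene = getattr(a, "gene_ids", None)
        name = gene[idx] if gene else f"node {idx}"
        raise ValueError(f"isolated node with zero degree: {name}")
    if n_eig is None:
        n_eig = default_n_eig(m)
    n_eig = int(min(max(n_eig, 3), m))

    d_isqrt = 1.0 / np.sqrt(deg)
    sym = av * d_isqrt[:, None] * d_isqrt[None, :]
    sym = 0.5 * (sym + sym.T)

    if m <= dense_threshold or n_eig >= m - 1:
        vals, vecs = scipy.linalg.eigh(sym)
        vals, vecs = vals[::-1], vecs[:, ::-1]
        vals, vecs = vals[:n_eig], vecs[:, :n_eig]
    else:
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(sym, k=n_eig, which="LA")
        except scipy.sparse.linalg.ArpackNoConvergence as err:
            raise RuntimeError(
                f"eigensolver failed to converge ({len(err.eigenvalues)} of "
                f"{n_eig} eigenpairs found); try a smaller n_eig"
            ) from err
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]

    # back-transform eigenvectors of the symmetric form to those of D^-1 A
    y = vecs * d_isqrt[:, None]

    # center, then scale to unit D-norm
    weights = deg @ y  # 1^T D y per column
    if centering == "printed_mean":
        y = y - weights[None, :] / m
    elif centering == "weighted_mean":
        y = y - weights[None, :] / deg.sum()
    else:
        raise ValueError(f"unknown centering rule: {centering!r}")
    dnorm = np.sqrt(np.einsum("ij,i,ij->j", y, deg, y))
    nonzero = dnorm > 1e-12
    y[:, nonzero] /= dnorm[nonzero]
    y = _sign_fix(y)

    return SpectralDecomposition(
        eigenvalues=vals.astype(float),
        vectors=y[:, 1:],  # drop the trivial leading column
        degrees=deg,
    )


def gap_profiles(
    eigenvalues: np.ndarray, k_max: int | None = None
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Eigengap objectives over the searched index range.

    With the spectrum sorted descending, for 1-based index i in
    [2, p - 2] (optionally further capped at ``k_max``):

    - additive gap:      lambda_i - lambda_{i+1}
    - relative gap:      (1 - lambda_{i+1}) / (1 - lambda_i)
    - second-order gap:  relative_gap(i) - relative_gap(i+1)

    Denominators are floored at ``EIGENGAP_EPS``: a repeated trivial
    eigenvalue (disconnected network) would otherwise divide by zero, and
    the floored ratio correctly spikes at the component count.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    p = len(lam)
    if p < 5:
        raise ValueError(f"need at least 5 eigenvalues to locate a gap, got {p}")
    hi = p - 2
    if k_max is not None:
        hi = min(hi, int(k_max))
    idx = np.arange(2, hi + 1)  # 1-based candidate indices

    one_minus = 1.0 - lam
    if (one_minus[1:] < EIGENGAP_EPS).any():
        logger.warning(
            "repeated trivial eigenvalue detected (disconnected network); "
            "flooring eigengap denominators at %g",
            EIGENGAP_EPS,
        )
    floored = np.maximum(one_minus, EIGENGAP_EPS)

    ag = lam[idx - 1] - lam[idx]
    rg_all = one_minus[1:] / floored[:-1]  # rg_all[i-1] = ratio at 1-based i
    rg = rg_all[idx - 1]
    sg = rg_all[idx - 1] - rg_all[idx]
    return {"ag": (idx, ag), "rg": (idx, rg), "sg": (idx, sg)}


def candidate_ks(
    sd: SpectralDecomposition | np.ndarray, k_max: int | None = None
) -> CandidateK:
    """Candidate cluster counts k_ag, k_rg, k_sg from the eigengap heuristics.

    Accepts a decomposition or a raw descending eigenvalue array.  Each
    candidate is the argmax of its gap objective over 1-based indices
    [2, n_computed - 2] (capped at ``k_max`` when given).
    """
    lam = sd.eigenvalues if isinstance(sd, SpectralDecomposition) else np.asarray(sd)
    profiles = gap_profiles(lam, k_max=k_max)
    picks = {}
    for method, (idx, obj) in profiles.items():
        picks[method] = int(idx[int(np.argmax(obj))])
    return CandidateK(picks["ag"], picks["rg"], picks["sg"], profiles)
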