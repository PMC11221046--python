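"""Planted-module synthetic data: expression matrices and GO annotations.

The expression generator plants equicorrelated gene modules through a
latent-factor model: each module draws one latent sample profile z, and a
member gene is sqrt(rho) * z + sqrt(1 - rho) * noise, giving pairwise
within-module correlation rho and (asymptotically) zero between-module
correlation.  The matched annotation generator gives each module a set of
signature GO terms covering a fraction of its genes (plus a sprinkle of
background genes so that foreign clusters still overlap the term), and a
pool of background terms annotated uniformly at random.  Term ids use a
synthetic "SYN:NNNNNNN" vocabulary with namespaces rotating over
BP/CC/MF so that all six enrichment queries are exercised.

Defaults describe the standard study condition: four modules of 100
genes, 30 samples, within-module correlation 0.8 and signature coverage
0.6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enrichment import NAMESPACES, AnnotationSet
from .network import ExpressionMatrix


@dataclass
class PlantedDesign:
    """Parameters of the planted-module generative model.

    ``noise_sd`` scales the overall expression amplitude; the
    within-module correlation is controlled by ``within_corr`` alone.
    ``term_coverage`` is the fraction of a module's genes annotated to
    each of its signature terms; ``background_annotation_rate`` is the
    per-gene probability that a signature term also annotates a gene
    outside its module.  ``background_terms`` random terms (sizes drawn
    from ``background_term_size``) model non-specific annotation.
    """

    m_per_module: tuple[int, ...] = (100, 100, 100, 100)
    n_samples: int = 30
    within_corr: float = 0.8
    noise_sd: float = 1.0
    n_terms_per_module: int = 12
    term_coverage: float = 0.6
    background_annotation_rate: float = 0.03
    background_terms: int = 100
    background_term_size: tuple[int, int] = (10, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.within_corr < 1:
            raise ValueError(f"within_corr must be in (0, 1): {self.within_corr}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be positive: {self.noise_sd}")
        if not 0 < self.term_coverage <= 1:
            raise ValueError(f"term_coverage must be in (0, 1]: {self.term_coverage}")
        if any(s < 1 for s in self.m_per_module):
            raise ValueError("module sizes must be positive")

    @property
    def n_genes(self) -> int:
        return sum(self.m_per_module)

    @property
    def n_modules(self) -> int:
        return len(self.m_per_module)


def generate_expression(design: PlantedDesign) -> tuple[ExpressionMatrix, np.ndarray]:
    """Planted-module expression matrix and true module labels (1-based)."""
    rng = np.random.default_rng(design.seed)
    rho = design.within_corr
    m, n = design.n_genes, design.n_samples
    k = design.n_modules
    if k >= n:
        raise ValueError(
            f"{k} orthogonal module profiles need more than {n} samples"
        )
    # Latent sample-profiles, orthogonalised in-sample: with few samples,
    # raw Gaussian draws carry spurious pairwise correlations ~ 1/sqrt(n)
    # that would plant genuine between-module correlation; QR removes it.
    raw = rng.normal(size=(n, k))
    raw -= raw.mean(axis=0)
    q, r = np.linalg.qr(raw)
    q *= np.sign(np.diag(r))  # deterministic orientation
    latents = (q * np.sqrt(n - 1)).T  # rows: unit-variance orthogonal profiles

    values = np.empty((m, n))
    labels = np.empty(m, dtype=int)
    row = 0
    for mod, size in enumerate(design.m_per_module, start=1):
        noise = rng.normal(size=(size, n))
        values[row : row + size] = design.noise_sd * (
            np.sqrt(rho) * latents[mod - 1][None, :] + np.sqrt(1.0 - rho) * noise
        )
        labels[row : row + size] = mod
        row += size
    gene_ids = [f"g{i + 1:04d}" for i in range(m)]
    sample_ids = [f"s{j + 1:02d}" for j in range(n)]
    return ExpressionMatrix(gene_ids, values, sample_ids), labels


def generate_annotation(
    design: PlantedDesign,
    labels: np.ndarray,
    gene_ids: list[str] | None = None,
    degraded_modules: tuple[int, ...] = (),
) -> AnnotationSet:
    """Matched annotation: signature terms per module plus background terms.

    Modules listed in ``degraded_modules`` get background-like signature
    terms (same sizes, genes drawn uniformly from the whole universe),
    destroying their planted enrichment while keeping the term count.
    Deterministic given the design seed (offset so that expression and
    annotation draws are independent).
    """
    labels = np.asarray(labels)
    m = len(labels)
    if gene_ids is None:
        gene_ids = [f"g{i + 1:04d}" for i in range(m)]
    rng = np.random.default_rng(design.seed + 1_000_003)
    universe = frozenset(gene_ids)
    gene_arr = np.array(gene_ids)
    mapping: dict[str, set[tuple[str, str]]] = {}
    term_no = 0

    def add(term: str, ns: str, genes) -> None:
        for g in genes:
            mapping.setdefault(str(g), set()).add((term, ns))

    for mod in range(1, design.n_modules + 1):
        members = gene_arr[labels == mod]
        outside = gene_arr[labels != mod]
        n_cov = max(1, round(design.term_coverage * len(members)))
        for _ in range(design.n_terms_per_module):
            term = f"SYN:{term_no:07d}"
            ns = NAMESPACES[term_no % len(NAMESPACES)]
            term_no += 1
            if mod in degraded_modules:
                # background-like: same size, genes from the whole universe
                n_bg = rng.binomial(len(outside), design.background_annotation_rate)
                genes = rng.choice(gene_arr, size=min(n_cov + n_bg, m), replace=False)
            else:
                covered = rng.choice(members, size=n_cov, replace=False)
                extra_mask = rng.random(len(outside)) < design.background_annotation_rate
                genes = np.concatenate([covered, outside[extra_mask]])
            add(term, ns, genes)

    lo, hi = design.background_term_size
    for _ in range(design.background_terms):
        term = f"SYN:{term_no:07d}"
        ns = NAMESPACES[term_no % len(NAMESPACES)]
        term_no += 1
        size = int(rng.integers(lo, hi + 1))
        add(term, ns, rng.choice(gene_arr, size=min(size, m), replace=False))

    return AnnotationSet(mapping, universe)


def annotation_to_frame(ann: AnnotationSet):
    """Long-format (gene, term, namespace) DataFrame, e.g. for writing TSV."""
    import pandas as pd

    rows = [
        (gene, term, ns)
        for gene in sorted(ann.mapping)
        for term, ns in sorted(ann.mapping[gene])
    ]
    return pd.DataFrame(rows, columns=["gene", "term", "namespace"])
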