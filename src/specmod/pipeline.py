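"""End-to-end orchestration of the five pipeline stages.

Given an expression matrix and a gene annotation, the pipeline builds the
TOM-enhanced co-expression network, embeds it spectrally, selects the
cluster count by eigengap candidates validated through test-cluster
enrichment, produces the *initial clusters*, then semi-labels genes from
the pooled top enrichment records and re-classifies the unremarkable
genes into the *final modules*.  Both partitions are returned (and
written, together with a run manifest, when an output directory is
given).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import classify, clustering, enrichment, network, semilabel, spectral
from .enrichment import AnnotationSet
from .network import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All user-tunable pipeline parameters with their defaults."""

    seed: int = 0
    bandwidth_sq: float | None = None
    variance_estimator: str = "population"
    n_eig: int | None = None
    k_max: int = spectral.DEFAULT_K_MAX
    k_override: int | None = None
    kmeans_n_init: int = clustering.DEFAULT_N_INIT
    kmeans_max_iter: int = clustering.DEFAULT_MAX_ITER
    p_cutoff: float = enrichment.DEFAULT_P_CUTOFF
    top_fraction: float = semilabel.DEFAULT_TOP_FRACTION
    classifier: str = "knn"
    quality_directions: str = "over"
    semilabel_directions: str = "both"
    centering: str = "printed_mean"
    nonfinite: str = "drop"
    refine: bool = True
    dump_network: bool = False

    def validated(self) -> "RunConfig":
        if not 0 < self.p_cutoff <= 1:
            raise ValueError(f"p_cutoff must be in (0, 1]: {self.p_cutoff}")
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1]: {self.top_fraction}")
        if self.classifier not in ("knn", "logistic"):
            raise ValueError(f"classifier must be knn|logistic: {self.classifier}")
        if self.k_override is not None and self.k_override < 2:
            raise ValueError(f"k override must be >= 2: {self.k_override}")
        if self.bandwidth_sq is not None and self.bandwidth_sq <= 0:
            raise ValueError(f"bandwidth must be positive: {self.bandwidth_sq}")
        return self


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus the run manifest."""

    gene_ids: list[str]
    adjacency: network.AdjacencyMatrix
    decomposition: spectral.SpectralDecomposition
    candidates: spectral.CandidateK | None
    initial: clustering.Clustering
    embedding: clustering.Embedding
    table: enrichment.EnrichmentTable
    semilabeling: semilabel.SemiLabeling | None
    modules: classify.ModuleSet | None
    manifest: dict = field(default_factory=dict)

    def module_labels(self) -> dict[str, int]:
        """Final module label per gene (initial clusters if refinement skipped)."""
        if self.modules is not None:
            return dict(self.modules.labels)
        return {
            g: int(c) for g, c in zip(self.gene_ids, self.initial.labels)
        }


def run_pipeline(
    ge: ExpressionMatrix,
    ann: AnnotationSet | None,
    cfg: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline; see the module docstring for the stages.

    ``ann`` may be None only when ``cfg.k_override`` is set and
    ``cfg.refine`` is False (no enrichment possible).  With
    ``cfg.refine`` False the pipeline stops after the initial clusters;
    the initial clusters are identical either way.
    """
    cfg = (cfg or RunConfig()).validated()
    if ann is None and (cfg.k_override is None or cfg.refine):
        raise ValueError(
            "an annotation set is required unless k is forced and refinement "
            "is disabled"
        )
    ge = ge.drop_nonfinite(policy=cfg.nonfinite)
    gene_ids = list(ge.gene_ids)

    # Stage 1: network construction
    _, sim, adj = network.build_network(
        ge, bandwidth_sq=cfg.bandwidth_sq, variance_estimator=cfg.variance_estimator
    )
    adj.gene_ids = gene_ids  # for error messages downstream

    # Stage 2: spectral embedding and cluster-count selection
    sd = spectral.decompose(adj, n_eig=cfg.n_eig, centering=cfg.centering)
    sd.gene_ids = gene_ids
    candidates = None
    if cfg.k_override is not None:
        emb = clustering.build_embedding(sd, cfg.k_override)
        cl = clustering.run_kmeans(
            emb, cfg.k_override, cfg.seed,
            n_init=cfg.kmeans_n_init, max_iter=cfg.kmeans_max_iter,
        )
        initial = clustering.with_conductances(adj, cl)
        method = "user"
    else:
        candidates = spectral.candidate_ks(sd, k_max=cfg.k_max)
        tests = clustering.select_test_clusters(
            adj, sd, candidates, cfg.seed,
            n_init=cfg.kmeans_n_init, max_iter=cfg.kmeans_max_iter,
        )
        results = {}
        for m, cl in tests.items():
            test_genes = [gene_ids[i] for i in cl.members(cl.test_cluster)]
            recs = enrichment.enrich_gene_set(
                test_genes, ann, cluster=cl.test_cluster, p_cutoff=cfg.p_cutoff
            )
            results[m] = (cl, enrichment.cluster_quality(
                recs, directions=cfg.quality_directions
            ))
        _, method, initial = clustering.choose_k(results)
        emb = clustering.build_embedding(sd, initial.k)
    initial = clustering.Clustering(
        labels=initial.labels, k=initial.k, method=method,
        conductances=initial.conductances, test_cluster=initial.test_cluster,
        gene_ids=gene_ids,
    )

    # Stage 3: enrichment of the chosen clustering
    table = enrichment.EnrichmentTable([])
    if ann is not None:
        table = enrichment.enrich_clusters(initial, ann, p_cutoff=cfg.p_cutoff)

    # Stages 4-5: semi-labeling and supervised re-classification
    sl = None
    modules = None
    if cfg.refine:
        if table.records:
            sl = semilabel.semi_label(
                table, initial, ann,
                top_fraction=cfg.top_fraction,
                directions=cfg.semilabel_directions,
            )
            modules = classify.train_and_classify(
                emb, sl, kind=cfg.classifier, seed=cfg.seed
            )
        else:
            logger.warning(
                "no enrichment records; skipping refinement, modules equal "
                "the initial clusters"
            )

    manifest = _manifest(cfg, initial, sl, modules, sd, candidates)
    result = PipelineResult(
        gene_ids=gene_ids,
        adjacency=adj,
        decomposition=sd,
        candidates=candidates,
        initial=initial,
        embedding=emb,
        table=table,
        semilabeling=sl,
        modules=modules,
        manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, outdir)
        if cfg.dump_network:
            from . import io as sio

            outdir = Path(outdir)
            sio.write_matrix_tsv(sim, gene_ids, outdir / "similarity.tsv.gz")
            sio.write_matrix_tsv(adj, gene_ids, outdir / "adjacency.tsv.gz")
    return result


def _manifest(cfg, initial, sl, modules, sd, candidates) -> dict:
    import sklearn

    import numpy
    import scipy

    from . import __version__

    man = {
        "config": asdict(cfg),
        "k": initial.k,
        "method": initial.method,
        "candidates": candidates.as_dict() if candidates is not None else None,
        "n_eigenvalues": sd.n_computed,
        "conductances": list(map(float, initial.conductances))
        if initial.conductances is not None else None,
        "test_cluster": initial.test_cluster,
        "versions": {
            "specmod": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if sl is not None and modules is not None:
        summary = classify.summarize_refinement(initial, sl, modules)
        man.update(
            k_prime=sl.k_prime,
            pct_unremarkable=summary["pct_unremarkable"],
            pct_changed=summary["pct_changed"],
            chosen_hyperparam=summary["chosen_hyperparam"],
            module_sizes=summary["module_sizes"],
        )
    return man


def write_outputs(result: PipelineResult, outdir: str | Path) -> dict[str, str]:
    """Write cluster/module TSVs, enrichment, conductance and the manifest.

    Returns the manifest (also written as JSON) including file hashes.
    """
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths = {}
    p = outdir / "initial_clusters.tsv"
    sio.write_labels_tsv(result.gene_ids, result.initial.labels, p)
    paths["initial_clusters"] = p

    labels = result.module_labels()
    p = outdir / "modules.tsv"
    sio.write_labels_tsv(
        result.gene_ids, [labels[g] for g in result.gene_ids], p, column="module"
    )
    paths["modules"] = p

    if result.initial.conductances is not None:
        import pandas as pd

        p = outdir / "conductance.tsv"
        pd.DataFrame(
            {
                "cluster": range(1, result.initial.k + 1),
                "conductance": result.initial.conductances,
            }
        ).to_csv(p, sep="\t", index=False)
        paths["conductance"] = p

    if result.table.records:
        p = outdir / "enrichment.tsv"
        result.table.to_dataframe().to_csv(p, sep="\t", index=False)
        paths["enrichment"] = p

    if result.semilabeling is not None:
        import pandas as pd

        sl = result.semilabeling
        p = outdir / "semilabel.tsv"
        pd.DataFrame(
            {
                "gene_id": result.gene_ids,
                "initial_cluster": result.initial.labels,
                "remarkable": [g in sl.remarkable for g in result.gene_ids],
                "training_label": [sl.remarkable.get(g, "NA") for g in result.gene_ids],
            }
        ).to_csv(p, sep="\t", index=False)
        paths["semilabel"] = p

    result.manifest["files"] = {
        name: {"path": str(path), "sha256": sio.sha256_of(path)}
        for name, path in paths.items()
    }
    sio.write_json(result.manifest, outdir / "manifest.json")
    return result.manifest
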