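"""Semi-labeling: split genes into remarkable and unremarkable.

The enrichment records of all clusters are pooled and the top fraction
(default 10%) with the smallest p-values is selected.  A gene is
*remarkable* when, within its own cluster, it is annotated to the term of
at least one selected record of that cluster; it then inherits the
cluster's label and becomes a training point.  All other genes are
unremarkable and will be re-classified.  Clusters left without any
remarkable gene are dropped, and the survivors are relabelled
contiguously, giving the refined cluster count k' <= k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .clustering import Clustering
from .enrichment import AnnotationSet, EnrichmentTable

logger = logging.getLogger(__name__)

DEFAULT_TOP_FRACTION = 0.10


@dataclass
class SemiLabeling:
    """Training labels for remarkable genes plus the unlabeled remainder.

    ``remarkable`` maps gene id -> contiguous training label in [1, k'];
    ``label_map`` maps surviving original cluster labels onto [1, k'].
    """

    remarkable: dict[str, int]
    unremarkable: set[str]
    k_prime: int
    label_map: dict[int, int]
    selected_records: list
    initial_cluster: dict[str, int]

    def initial_mapped_label(self, gene: str) -> int | None:
        """The gene's initial cluster mapped into [1, k'], or None if dropped."""
        return self.label_map.get(self.initial_cluster[gene])

    @property
    def n_remarkable(self) -> int:
        return len(self.remarkable)


def select_top_records(table: EnrichmentTable, top_fraction: float) -> list:
    """The ceil(top_fraction * total) records with the smallest p-values.

    Ties at the boundary p-value are resolved deterministically by
    (cluster, term id, direction) lexical order.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    records = sorted(
        table.records, key=lambda r: (r.p_value, r.cluster, r.term_id, r.direction)
    )
    n_select = math.ceil(top_fraction * len(records))
    return records[:n_select]


def semi_label(
    table: EnrichmentTable,
    clustering: Clustering,
    ann: AnnotationSet,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    directions: str = "both",
) -> SemiLabeling:
    """Derive remarkable-gene training labels from the pooled top records.

    ``directions`` restricts the pooled records to one test direction
    ("over"/"under") or keeps "both" (default).

    Raises
    ------
    ValueError
        If the enrichment table is empty (nothing can be selected);
        consider a larger ``top_fraction`` or p-value cutoff.
    """
    if clustering.gene_ids is None:
        raise ValueError("clustering carries no gene identifiers")
    pool = table
    if directions != "both":
        pool = EnrichmentTable([r for r in table.records if r.direction == directions])
    if not pool.records:
        raise ValueError(
            "no enrichment records to select from; increase top_fraction or "
            "the enrichment p-value cutoff"
        )
    selected = select_top_records(pool, top_fraction)

    # cluster -> union of genes annotated to that cluster's selected terms
    selected_genes: dict[int, set[str]] = {}
    for rec in selected:
        genes = ann.term_genes.get(rec.term_id, frozenset())
        selected_genes.setdefault(rec.cluster, set()).update(genes)

    remarkable_by_cluster: dict[int, set[str]] = {}
    unremarkable: set[str] = set()
    for gene, label in zip(clustering.gene_ids, clustering.labels):
        label = int(label)
        if gene in selected_genes.get(label, ()):  # own-cluster terms only
            remarkable_by_cluster.setdefault(label, set()).add(gene)
        else:
            unremarkable.add(gene)

    surviving = sorted(remarkable_by_cluster)
    label_map = {orig: i + 1 for i, orig in enumerate(surviving)}
    dropped = [c for c in range(1, clustering.k + 1) if c not in label_map]
    if dropped:
        logger.info("clusters without remarkable genes dropped: %s", dropped)
    remarkable = {
        gene: label_map[orig]
        for orig, genes in remarkable_by_cluster.items()
        for gene in genes
    }
    return SemiLabeling(
        remarkable=remarkable,
        unremarkable=unremarkable,
        k_prime=len(surviving),
        label_map=label_map,
        selected_records=selected,
        initial_cluster={
            g: int(c) for g, c in zip(clustering.gene_ids, clustering.labels)
        },
    )
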