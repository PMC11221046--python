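"""Per-cluster GO over/under-representation analysis.

Every (cluster, term) pair with at least one annotated cluster member is
tested with a plain hypergeometric test in both directions, for each
ontology namespace (BP, CC, MF), against the universe of all genes in the
dataset.  Reported fields mirror the familiar over-representation report:
p-value, odds ratio, expected count, count and term size.  p-values are
raw by default (an optional Benjamini-Hochberg flag is provided); no GO
DAG conditioning or annotation propagation is performed -- annotations
are used exactly as given.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "CC", "MF")
DIRECTIONS = ("over", "under")
DEFAULT_P_CUTOFF = 0.05
_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


@dataclass
class AnnotationSet:
    """Gene -> GO-term annotation restricted to a gene universe.

    ``mapping`` holds, for each annotated gene, the set of (term id,
    namespace) pairs; genes of the universe absent from ``mapping`` are
    unannotated.  Derived indexes (term -> gene set, term -> namespace)
    are built on construction.
    """

    mapping: dict[str, set[tuple[str, str]]]
    universe: frozenset[str]
    term_genes: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    term_namespace: dict[str, str] = field(default_factory=dict, repr=False)
    term_names: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.term_genes:
            tg: dict[str, set[str]] = {}
            for gene, terms in self.mapping.items():
                if gene not in self.universe:
                    raise ValueError(f"annotated gene {gene!r} not in universe")
                for term, ns in terms:
                    tg.setdefault(term, set()).add(gene)
                    prev = self.term_namespace.setdefault(term, ns)
                    if prev != ns:
                        logger.warning(
                            "term %s seen with namespaces %s and %s; keeping %s",
                            term, prev, ns, prev,
                        )
            self.term_genes = {t: frozenset(g) for t, g in tg.items()}

    @property
    def n_terms(self) -> int:
        return len(self.term_genes)

    def coverage(self) -> float:
        """Fraction of the universe carrying at least one annotation."""
        return len(self.mapping) / max(len(self.universe), 1)

    def annotated_terms(self, genes) -> set[str]:
        out: set[str] = set()
        for g in genes:
            out.update(t for t, _ in self.mapping.get(g, ()))
        return out


@dataclass
class EnrichmentRecord:
    """One tested (cluster, term, direction) with its report fields."""

    cluster: int
    term_id: str
    namespace: str
    direction: str
    p_value: float
    odds_ratio: float
    expected_count: float
    count: int
    size: int


@dataclass
class EnrichmentTable:
    """Retained enrichment records across all clusters and queries."""

    records: list[EnrichmentRecord]

    def for_cluster(self, cluster: int) -> list[EnrichmentRecord]:
        return [r for r in self.records if r.cluster == cluster]

    def clusters(self) -> list[int]:
        return sorted({r.cluster for r in self.records})

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "cluster": r.cluster,
                    "term_id": r.term_id,
                    "namespace": r.namespace,
                    "direction": r.direction,
                    "p_value": r.p_value,
                    "odds_ratio": r.odds_ratio,
                    "expected_count": r.expected_count,
                    "count": r.count,
                    "size": r.size,
                }
                for r in self.records
            ],
            columns=[
                "cluster", "term_id", "namespace", "direction",
                "p_value", "odds_ratio", "expected_count", "count", "size",
            ],
        )


def _parse_simple_tsv(path, sep: str) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise ValueError(f"annotation line has fewer than 2 columns: {line!r}")
            gene, term = parts[0].strip(), parts[1].strip()
            ns = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "BP"
            rows.append((gene, term, ns))
    return rows


def _parse_gaf(path) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            qualifier = parts[3]
            if "NOT" in qualifier.split("|"):
                continue
            ns = _GAF_ASPECT.get(parts[8])
            if ns is None:
                continue
            # DB object id and symbol both recorded; matched later
            rows.append((parts[1], parts[4], ns))
            if parts[2] and parts[2] != parts[1]:
                rows.append((parts[2], parts[4], ns))
    return rows


def load_annotation(path, universe, fmt: str | None = None) -> AnnotationSet:
    """Load a gene -> GO-term table and restrict it to the gene universe.

    Accepts a plain 2/3-column table (gene, term[, namespace]; tab or
    comma separated, namespace defaulting to BP) or GAF 2.x (detected by
    a ``.gaf`` suffix or the ``!gaf-version`` header; NOT-qualified lines
    are skipped, and both the DB object id and symbol are matched against
    the universe).  Header skipped automatically if the first line's
    gene is absent from the universe and looks like a label.
    """
    universe = frozenset(universe)
    path = str(path)
    if fmt is None:
        if path.endswith(".gaf"):
            fmt = "gaf"
        else:
            with open(path) as fh:
                first = fh.readline()
            fmt = "gaf" if first.startswith("!gaf") else "tsv"
    if fmt == "gaf":
        rows = _parse_gaf(path)
    else:
        sep = "," if path.endswith(".csv") else "\t"
        rows = _parse_simple_tsv(path, sep)
        if rows and rows[0][0] not in universe and rows[0][0].lower() in (
            "gene", "gene_id", "geneid", "symbol"
        ):
            rows = rows[1:]
    if not rows:
        raise ValueError(f"no annotation rows parsed from {path}")

    mapping: dict[str, set[tuple[str, str]]] = {}
    for gene, term, ns in rows:
        if gene in universe:
            mapping.setdefault(gene, set()).add((term, ns))
    if not mapping:
        raise ValueError(
            f"annotation file {path} shares no genes with the expression data"
        )
    ann = AnnotationSet(mapping, universe)
    logger.info(
        "annotation: %d/%d genes covered (%.1f%%), %d terms",
        len(mapping), len(universe), 100 * ann.coverage(), ann.n_terms,
    )
    return ann


def load_term_names(obo_path) -> dict[str, str]:
    """Term id -> human-readable name from an OBO file (names only).

    Only ``[Term]`` stanzas' ``id:`` and ``name:`` lines are read; the
    ontology graph itself is never used.
    """
    names: dict[str, str] = {}
    term_id = None
    in_term = False
    with open(obo_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                in_term = line == "[Term]"
                term_id = None
            elif in_term and line.startswith("id:"):
                term_id = line[3:].strip()
            elif in_term and line.startswith("name:") and term_id:
                names[term_id] = line[5:].strip()
    return names


def hypergeom_test(
    cluster_genes: set[str],
    term_genes: set[str],
    universe: set[str] | frozenset[str],
    direction: str = "over",
) -> dict:
    """Hypergeometric over/under-representation of a term in a cluster.

    With N the universe size, K the term size, n the cluster size and x
    the overlap, the over-representation p-value is P[X >= x] and the
    under-representation p-value P[X <= x] for X ~ Hypergeom(N, K, n).
    The odds ratio is x (N - K - n + x) / ((K - x)(n - x)), reported as
    0 when x = 0 and +inf when the denominator vanishes with x > 0.
    """
    N = len(universe)
    K = len(term_genes)
    n = len(cluster_genes)
    if K == 0 or n == 0:
        raise ValueError("term and cluster must be non-empty within the universe")
    if not set(cluster_genes) <= set(universe) or not set(term_genes) <= set(universe):
        raise ValueError("cluster and term genes must be subsets of the universe")
    x = len(set(cluster_genes) & set(term_genes))
    if direction == "over":
        p = float(hypergeom.sf(x - 1, N, K, n))
    elif direction == "under":
        p = float(hypergeom.cdf(x, N, K, n))
    else:
        raise ValueError(f"direction must be 'over' or 'under', got {direction!r}")
    p = min(max(p, 0.0), 1.0)
    if x == 0:
        odds = 0.0
    else:
        denom = (K - x) * (n - x)
        odds = math.inf if denom == 0 else x * (N - K - n + x) / denom
    return {
        "p_value": p,
        "odds_ratio": odds,
        "expected_count": n * K / N,
        "count": x,
        "size": K,
    }


def enrich_gene_set(
    genes,
    ann: AnnotationSet,
    cluster: int = 0,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> list[EnrichmentRecord]:
    """Test one gene set against every term it touches, both directions.

    Returns records with p <= p_cutoff sorted by ascending p (ties by
    term id then direction).  Terms with fewer than 2 annotated genes are
    tested like any other (no silent size filtering).
    """
    genes = set(genes) & set(ann.universe)
    records: list[EnrichmentRecord] = []
    if not genes:
        return records
    for term in sorted(ann.annotated_terms(genes)):
        tg = ann.term_genes[term]
        ns = ann.term_namespace[term]
        for direction in DIRECTIONS:
            res = hypergeom_test(genes, tg, ann.universe, direction)
            if res["p_value"] <= p_cutoff:
                records.append(
                    EnrichmentRecord(
                        cluster=cluster,
                        term_id=term,
                        namespace=ns,
                        direction=direction,
                        **res,
                    )
                )
    records.sort(key=lambda r: (r.p_value, r.term_id, r.direction))
    return records


def enrich_clusters(
    clustering,
    ann: AnnotationSet,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> EnrichmentTable:
    """Enrichment of every cluster, all six queries (over/under x BP/CC/MF).

    ``clustering`` must carry gene identifiers.  Clusters with no
    annotated gene contribute no records (logged).  Records are sorted by
    ascending p within each cluster.
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    records: list[EnrichmentRecord] = []
    for cluster, genes in clustering.gene_sets().items():
        recs = enrich_gene_set(genes, ann, cluster=cluster, p_cutoff=p_cutoff)
        if not recs and not ann.annotated_terms(genes):
            logger.warning("cluster %d has no annotated genes", cluster)
        records.extend(recs)
    return EnrichmentTable(records)


def cluster_quality(records, directions: str = "over") -> float:
    """Enrichment quality of one cluster: sum of -log10 p over its records.

    ``directions`` limits the sum to "over" (the default), "under", or
    "both".  Over-representation only is the default because an
    under-representation record scores what a cluster *excludes*: summing
    those systematically favours coarse clusterings whose complement
    excludes entire modules.  An empty record list scores 0.
    """
    total = 0.0
    for r in records:
        if directions != "both" and r.direction != directions:
            continue
        total += -math.log10(max(r.p_value, 1e-320))
    return total


def benjamini_hochberg(table: EnrichmentTable) -> EnrichmentTable:
    """Optional BH adjustment of the p-values across the whole table."""
    if not table.records:
        return table
    p = np.array([r.p_value for r in table.records])
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_end, i in enumerate(order[::-1]):
        rank = n - rank_from_end
        running = min(running, p[i] * n / rank)
        adj[i] = running
    recs = [
        EnrichmentRecord(
            r.cluster, r.term_id, r.namespace, r.direction,
            float(q), r.odds_ratio, r.expected_count, r.count, r.size,
        )
        for r, q in zip(table.records, adj)
    ]
    return EnrichmentTable(recs)
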