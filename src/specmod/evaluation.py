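"""Comparison metrics over module enrichment tables.

Module quality q_j averages the -log10 p-values of the GO terms retained
for module j; framework quality Q_f averages q_j over the modules.  The
*prominent* module is the one containing the globally most significant
term; its top-10 p-values and top-100 unique term ids support
cross-framework comparison, including the overlap in reported terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .enrichment import EnrichmentTable

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-320


@dataclass
class FrameworkReport:
    """Summary metrics for one framework's enrichment table."""

    module_qualities: dict[int, float]
    framework_quality: float
    pooled_p_values: list[float]
    pooled_mean_neglog10: float
    top100_p_values: list[float]
    prominent_module: int
    prominent_top10_p: list[float]
    prominent_top100_terms: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "module_qualities": self.module_qualities,
            "framework_quality": self.framework_quality,
            "pooled_mean_neglog10": self.pooled_mean_neglog10,
            "top100_p_values": self.top100_p_values,
            "prominent_module": self.prominent_module,
            "prominent_top10_p": self.prominent_top10_p,
            "prominent_top100_terms": self.prominent_top100_terms,
        }


def _neglog10(p: float) -> float:
    return -math.log10(max(p, _LOG_FLOOR))


def framework_quality(table: EnrichmentTable) -> FrameworkReport:
    """Per-module qualities q_j, framework quality Q_f and ranked p lists.

    q_j = -(sum_i log10 p_{i,j}) / n_j over the n_j terms retained for
    module j; Q_f is the mean of q_j over modules with n_j > 0 (empty
    modules are excluded with a logged count).
    """
    by_module: dict[int, list[float]] = {}
    for r in table.records:
        by_module.setdefault(r.cluster, []).append(r.p_value)
    if not by_module:
        raise ValueError("enrichment table is empty; no module qualities to compute")

    qualities = {
        j: sum(_neglog10(p) for p in ps) / len(ps) for j, ps in by_module.items()
    }
    pooled = sorted(p for ps in by_module.values() for p in ps)
    q_f = sum(qualities.values()) / len(qualities)

    prom = prominent_module(table)
    return FrameworkReport(
        module_qualities=dict(sorted(qualities.items())),
        framework_quality=q_f,
        pooled_p_values=pooled,
        pooled_mean_neglog10=sum(_neglog10(p) for p in pooled) / len(pooled),
        top100_p_values=pooled[:100],
        prominent_module=prom[0],
        prominent_top10_p=prom[1],
        prominent_top100_terms=prom[2],
    )


def prominent_module(table: EnrichmentTable) -> tuple[int, list[float], list[str]]:
    """Module holding the most significant term, with its top lists.

    Returns (module id, its 10 smallest p-values, its top-100 unique term
    ids ranked by smallest p).  A term reported in both directions counts
    once with its smallest p.  A global tie goes to the smaller module id.
    """
    if not table.records:
        raise ValueError("enrichment table is empty")
    best = min(table.records, key=lambda r: (r.p_value, r.cluster))
    module = best.cluster
    ps = sorted(r.p_value for r in table.records if r.cluster == module)
    term_best: dict[str, float] = {}
    for r in table.records:
        if r.cluster != module:
            continue
        prev = term_best.get(r.term_id)
        if prev is None or r.p_value < prev:
            term_best[r.term_id] = r.p_value
    top_terms = [t for t, _ in sorted(term_best.items(), key=lambda kv: (kv[1], kv[0]))]
    return module, ps[:10], top_terms[:100]


def term_overlap(report_a: FrameworkReport, report_b: FrameworkReport) -> int:
    """Number of term ids shared by the two top-100 unique term lists."""
    return len(set(report_a.prominent_top100_terms) & set(report_b.prominent_top100_terms))
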