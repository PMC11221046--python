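"""Hypergeometric enrichment: exactness, parsing and invariants."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specmod import (
    AnnotationSet,
    Clustering,
    cluster_quality,
    enrich_clusters,
    hypergeom_test,
    load_annotation,
)
from specmod.enrichment import benjamini_hochberg


def exact_tail(N: int, K: int, n: int, x: int, direction: str) -> Fraction:
    """Rational-arithmetic hypergeometric tail sum."""
    total = math.comb(N, n)
    lo, hi = (x, min(K, n)) if direction == "over" else (max(0, n - (N - K)), x)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(lo, hi + 1))
    return Fraction(num, total)


def make_universe(n: int) -> list[str]:
    return [f"g{i:03d}" for i in range(n)]


def simple_annotation(term_sets: dict[str, list[str]], universe) -> AnnotationSet:
    mapping: dict[str, set] = {}
    for i, (term, genes) in enumerate(term_sets.items()):
        ns = ["BP", "CC", "MF"][i % 3]
        for g in genes:
            mapping.setdefault(g, set()).add((term, ns))
    return AnnotationSet(mapping, frozenset(universe))


class TestHypergeomTest:
    def test_worked_case(self):
        u = set(make_universe(20))
        term = set(make_universe(5))
        clus = set(make_universe(10))
        res = hypergeom_test(clus, term, u, "over")
        assert res["p_value"] == pytest.approx(3003 / 184756, rel=1e-12)
        assert res["expected_count"] == pytest.approx(2.5)
        assert res["count"] == 5 and res["size"] == 5

    def test_no_overlap_over_p_is_one(self):
        u = make_universe(12)
        res = hypergeom_test(set(u[:4]), set(u[8:]), set(u), "over")
        assert res["p_value"] == pytest.approx(1.0)
        assert res["odds_ratio"] == 0.0

    def test_odds_ratio_degenerate_cells(self):
        u = make_universe(10)
        # term == cluster: (K - x)(n - x) = 0 with x > 0 -> +inf
        res = hypergeom_test(set(u[:4]), set(u[:4]), set(u), "over")
        assert res["odds_ratio"] == math.inf

    @pytest.mark.parametrize(
        "N,K,n", [(15, 4, 6), (20, 5, 10), (25, 12, 7), (30, 3, 15)]
    )
    def test_matches_rational_oracle(self, N, K, n):
        u = make_universe(N)
        term = set(u[:K])
        for x in range(0, min(K, n) + 1):
            clus = set(u[:x]) | set(u[K : K + n - x])
            for direction in ("over", "under"):
                res = hypergeom_test(clus, term, set(u), direction)
                expect = float(exact_tail(N, K, n, x, direction))
                assert res["p_value"] == pytest.approx(expect, rel=1e-10)

    def test_empty_inputs_rejected(self):
        u = set(make_universe(10))
        with pytest.raises(ValueError):
            hypergeom_test(set(), set(u), u, "over")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(5, 30), st.data())
    def test_tail_monotonicity_and_atom_overlap(self, N, data):
        """over-p non-increasing in x, under-p non-decreasing, sum >= 1."""
        K = data.draw(st.integers(1, N - 1))
        n = data.draw(st.integers(1, N - 1))
        u = make_universe(N)
        term = set(u[:K])
        prev_over, prev_under = None, None
        for x in range(max(0, n - (N - K)), min(K, n) + 1):
            clus = set(u[:x]) | set(u[K : K + n - x])
            over = hypergeom_test(clus, term, set(u), "over")["p_value"]
            under = hypergeom_test(clus, term, set(u), "under")["p_value"]
            assert over + under >= 1.0 - 1e-12  # shared P[X = x] atom
            if prev_over is not None:
                assert over <= prev_over + 1e-12
                assert under >= prev_under - 1e-12
            prev_over, prev_under = over, under


class TestLoadAnnotation:
    def test_simple_tsv(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("g1\tT1\ng2\tT1\ng3\tT2\tMF\ng1\tT1\n")
        ann = load_annotation(p, ["g1", "g2", "g3", "g4"])
        assert set(ann.mapping) == {"g1", "g2", "g3"}
        assert ann.term_genes["T1"] == {"g1", "g2"}  # duplicates collapse
        assert ann.term_namespace["T2"] == "MF"
        assert ann.term_namespace["T1"] == "BP"  # namespace default
        assert "g4" not in ann.mapping

    def test_gaf_not_qualifier_skipped(self, tmp_path):
        gaf = tmp_path / "test.gaf"
        cols = ["DB", "g1", "G1SYM", "", "GO:0001", "ref", "IEA", "", "P"] + [""] * 8
        not_cols = list(cols)
        not_cols[1], not_cols[3], not_cols[4] = "g2", "NOT", "GO:0002"
        gaf.write_text(
            "!gaf-version: 2.2\n" + "\t".join(cols) + "\n" + "\t".join(not_cols) + "\n"
        )
        ann = load_annotation(gaf, ["g1", "g2"])
        assert "GO:0001" in ann.term_genes
        assert "GO:0002" not in ann.term_genes

    def test_zero_overlap_rejected(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("gX\tT1\n")
        with pytest.raises(ValueError, match="no genes"):
            load_annotation(p, ["g1", "g2"])


class TestEnrichClusters:
    def _fixture(self):
        u = make_universe(20)
        ann = simple_annotation({"T1": u[:10], "T2": u[10:14], "T3": u}, u)
        labels = np.array([1] * 10 + [2] * 10)
        cl = Clustering(labels=labels, k=2, gene_ids=u)
        return u, ann, cl

    def test_cluster_equal_to_half_universe_term(self):
        u, ann, cl = self._fixture()
        table = enrich_clusters(cl, ann, p_cutoff=1.0)
        rec = next(
            r for r in table.records
            if r.cluster == 1 and r.term_id == "T1" and r.direction == "over"
        )
        # cluster 1 == T1 genes exactly: p = 1 / C(20,10)
        assert rec.p_value == pytest.approx(1 / 184756, rel=1e-9)
        expect = float(exact_tail(20, 10, 10, 10, "over"))
        assert rec.p_value == pytest.approx(expect, rel=1e-9)

    def test_cutoff_one_keeps_every_tested_query(self):
        u, ann, cl = self._fixture()
        table = enrich_clusters(cl, ann, p_cutoff=1.0)
        # every (cluster, term, direction) with >= 1 annotated member present
        got = {(r.cluster, r.term_id, r.direction) for r in table.records}
        assert ("1", ) not in got
        assert ("T2",) not in got
        assert (1, "T1", "over") in got and (1, "T1", "under") in got
        assert (2, "T2", "over") in got
        assert (1, "T2", "over") not in got  # no T2 gene in cluster 1
        for r in table.records:
            assert r.count >= 1

    def test_sorted_by_p_within_cluster(self):
        u, ann, cl = self._fixture()
        table = enrich_clusters(cl, ann, p_cutoff=1.0)
        for c in table.clusters():
            ps = [r.p_value for r in table.for_cluster(c)]
            assert ps == sorted(ps)

    def test_gene_renaming_invariance(self):
        u, ann, cl = self._fixture()
        table = enrich_clusters(cl, ann, p_cutoff=1.0)
        renamed = {g: f"x_{g}" for g in u}
        ann2 = AnnotationSet(
            {renamed[g]: set(ts) for g, ts in ann.mapping.items()},
            frozenset(renamed.values()),
        )
        cl2 = Clustering(labels=cl.labels, k=2, gene_ids=[renamed[g] for g in u])
        table2 = enrich_clusters(cl2, ann2, p_cutoff=1.0)
        ps1 = sorted((r.cluster, r.term_id, r.direction, r.p_value)
                     for r in table.records)
        ps2 = sorted((r.cluster, r.term_id, r.direction, r.p_value)
                     for r in table2.records)
        assert ps1 == ps2


class TestClusterQuality:
    def _records(self, ps, direction="over"):
        return [
            type("R", (), {"p_value": p, "direction": direction})() for p in ps
        ]

    def test_arithmetic(self):
        assert cluster_quality(self._records([1e-3, 1e-5])) == pytest.approx(8.0)
        assert cluster_quality([]) == 0.0
        base = cluster_quality(self._records([1e-3]))
        more = cluster_quality(self._records([1e-3, 0.1]))
        assert more - base == pytest.approx(1.0)

    def test_direction_filter(self):
        recs = self._records([1e-3]) + self._records([1e-5], "under")
        assert cluster_quality(recs, directions="over") == pytest.approx(3.0)
        assert cluster_quality(recs, directions="both") == pytest.approx(8.0)


def test_benjamini_hochberg_monotone():
    u = make_universe(30)
    ann = simple_annotation({"T1": u[:10], "T2": u[:5], "T3": u[20:]}, u)
    cl = Clustering(labels=np.array([1] * 15 + [2] * 15), k=2, gene_ids=u)
    table = enrich_clusters(cl, ann, p_cutoff=1.0)
    adj = benjamini_hochberg(table)
    raw = np.array([r.p_value for r in table.records])
    q = np.array([r.p_value for r in adj.records])
    assert np.all(q >= raw - 1e-15)
    assert np.all(q <= 1.0 + 1e-15)
    order = np.argsort(raw)
    assert np.all(np.diff(q[order]) >= -1e-12)
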