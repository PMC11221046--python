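"""Network construction: unit normalisation, Gaussian kernel, TOM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specmod import (
    ExpressionMatrix,
    NormalizedExpression,
    SimilarityMatrix,
    estimate_bandwidth,
    gaussian_similarity,
    normalize_genes,
    tom_enhance,
)
from specmod.network import pairwise_sq_distances

from conftest import random_expression


def naive_similarity(g: np.ndarray, bw: float) -> np.ndarray:
    m = g.shape[0]
    s = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            d2 = float(np.sum((g[i] - g[j]) ** 2))
            s[i, j] = np.exp(-d2 / (2 * bw))
    return s


def naive_tom(s: np.ndarray) -> np.ndarray:
    """Triple-loop oracle: l sums over u outside {i, j}; k excludes diagonal."""
    m = s.shape[0]
    a = np.zeros((m, m))
    k = np.array([sum(s[i, u] for u in range(m) if u != i) for i in range(m)])
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            l = sum(s[i, u] * s[u, j] for u in range(m) if u not in (i, j))
            a[i, j] = (l + s[i, j]) / (min(k[i], k[j]) + 1 - s[i, j])
    return a


class TestNormalizeGenes:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([3.0, 4.0], [0.6, 0.8]),
            ([0.6, 0.8], [0.6, 0.8]),
            ([1.0, 1.0, 1.0, 1.0], [0.5, 0.5, 0.5, 0.5]),
        ],
    )
    def test_known_rows(self, row, expected):
        ge = ExpressionMatrix(["a", "b", "c"], np.array([row, row, row]))
        g = normalize_genes(ge)
        np.testing.assert_allclose(g.values[0], expected, atol=1e-15)

    def test_idempotent(self, rng):
        ge = random_expression(rng, m=12, n=5)
        once = normalize_genes(ge).values
        twice = normalize_genes(
            ExpressionMatrix(ge.gene_ids, once)
        ).values
        np.testing.assert_allclose(once, twice, atol=1e-12)
        np.testing.assert_allclose(np.linalg.norm(once, axis=1), 1.0, atol=1e-10)

    def test_zero_row_rejected_with_gene_name(self):
        vals = np.ones((3, 4))
        vals[1] = 0.0
        with pytest.raises(ValueError, match="gBAD"):
            normalize_genes(ExpressionMatrix(["g0", "gBAD", "g2"], vals))


def rows_with_sq_distances(d2_matrix: np.ndarray) -> np.ndarray:
    """Unit rows realising given pairwise squared distances (via the Gram matrix)."""
    gram = 1.0 - d2_matrix / 2.0
    chol = np.linalg.cholesky(gram + 1e-12 * np.eye(len(gram)))
    return chol


class TestBandwidth:
    def test_equidistant_rows_rejected(self):
        # three mutually equidistant unit rows: zero variance
        g = NormalizedExpression(["a", "b", "c"], np.eye(3))
        with pytest.raises(ValueError, match="variance"):
            estimate_bandwidth(g)

    def test_listed_distances(self):
        d2 = np.array([[0, 0.5, 1.0], [0.5, 0, 1.5], [1.0, 1.5, 0]])
        rows = rows_with_sq_distances(d2)
        g = NormalizedExpression(["a", "b", "c"], rows)
        np.testing.assert_allclose(pairwise_sq_distances(g), [0.5, 1.0, 1.5],
                                   atol=1e-8)
        assert estimate_bandwidth(g) == pytest.approx(1 / 6, abs=1e-8)
        assert estimate_bandwidth(g, estimator="sample") == pytest.approx(0.25,
                                                                          abs=1e-8)

    def test_duplicated_genes_recomputed_brute_force(self, rng):
        ge = random_expression(rng, m=6, n=4)
        g = normalize_genes(ge)
        doubled = NormalizedExpression(
            [f"{gid}{tag}" for tag in ("", "_dup") for gid in g.gene_ids],
            np.vstack([g.values, g.values]),
        )
        d2 = []
        v = doubled.values
        for i in range(len(v)):
            for j in range(i + 1, len(v)):
                d2.append(np.sum((v[i] - v[j]) ** 2))
        assert estimate_bandwidth(doubled) == pytest.approx(np.var(d2), rel=1e-10)


class TestGaussianSimilarity:
    def test_zero_distance_and_forced_value(self):
        bw = 0.3
        rows = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        # d^2(row0, row2) = 2; pick bw so 2 = 2*bw => s = e^-1
        s = gaussian_similarity(NormalizedExpression(list("abc"), rows), 1.0)
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(np.exp(-1), abs=1e-12)
        with pytest.raises(ValueError):
            gaussian_similarity(NormalizedExpression(list("abc"), rows), -bw)

    def test_dot_product_identity_on_unit_rows(self, rng):
        ge = random_expression(rng, m=15, n=8)
        g = normalize_genes(ge)
        bw = 0.7
        s = gaussian_similarity(g, bw)
        dots = g.values @ g.values.T
        np.testing.assert_allclose(s.values, np.exp((dots - 1) / bw), atol=1e-10)

    def test_sample_permutation_invariance(self, rng):
        ge = random_expression(rng, m=10, n=6)
        g = normalize_genes(ge)
        perm = rng.permutation(6)
        g_perm = NormalizedExpression(g.gene_ids, g.values[:, perm])
        s1 = gaussian_similarity(g, 0.5).values
        s2 = gaussian_similarity(g_perm, 0.5).values
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestTomEnhance:
    def test_three_genes_all_half(self):
        s = np.full((3, 3), 0.5)
        np.fill_diagonal(s, 1.0)
        a = tom_enhance(SimilarityMatrix(s, 1.0)).values
        # l12 = s13*s32 = 0.25, k_i = 1.0 => a12 = 0.75 / 1.5 = 0.5
        assert a[0, 1] == pytest.approx(0.5, abs=1e-15)
        assert np.all(np.diag(a) == 0)

    def test_two_positive_pair_reduces_to_similarity(self):
        # an isolated positive pair embedded among disconnected genes
        s = np.eye(4)
        s[0, 1] = s[1, 0] = 0.8
        a = tom_enhance(SimilarityMatrix(s, 1.0)).values
        assert a[0, 1] == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("m", [3, 7, 12, 20])
    def test_matches_triple_loop_oracle(self, m, rng):
        s = rng.uniform(0, 1, size=(m, m))
        s = 0.5 * (s + s.T)
        np.fill_diagonal(s, 1.0)
        a = tom_enhance(SimilarityMatrix(s, 1.0)).values
        np.testing.assert_allclose(a, naive_tom(s), atol=1e-12)
        assert a.min() >= 0 and a.max() <= 1

    def test_gene_permutation_consistency(self, rng):
        ge = random_expression(rng, m=9, n=5)
        g = normalize_genes(ge)
        s = gaussian_similarity(g, 0.4)
        a = tom_enhance(s).values
        perm = rng.permutation(9)
        s_p = SimilarityMatrix(s.values[np.ix_(perm, perm)], 0.4)
        a_p = tom_enhance(s_p).values
        np.testing.assert_allclose(a_p, a[np.ix_(perm, perm)], atol=1e-12)

    def test_identical_rows_stay_bounded(self, rng):
        ge = random_expression(rng, m=8, n=5)
        ge.values[3] = ge.values[5]  # identical genes
        g = normalize_genes(ge)
        a = tom_enhance(gaussian_similarity(g, 0.5)).values
        assert np.isfinite(a).all()
        assert a.max() <= 1.0 + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_similarity_tom_oracle_property(seed):
    """Full S and A reproduced by the naive oracle on random fixtures."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(4, 15))
    ge = random_expression(rng, m=m, n=int(rng.integers(3, 8)))
    g = normalize_genes(ge)
    bw = estimate_bandwidth(g)
    s = gaussian_similarity(g, bw)
    np.testing.assert_allclose(s.values, naive_similarity(g.values, bw), atol=1e-12)
    a = tom_enhance(s)
    np.testing.assert_allclose(a.values, naive_tom(s.values), atol=1e-12)
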