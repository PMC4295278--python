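import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexpair.coexpr import (
    build_base_network,
    correlation_pvalue,
    pairwise_correlation,
    pearson,
    spearman,
)
from coexpair.errors import InputError, UndefinedCorrelationError

from .conftest import make_class_map, make_matrix


def pearson_oracle(x, y):
    """Literal product-moment summation formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def midrank(values):
    """Mid-rank (average rank) vector, brute force."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestPearson:
    def test_exact_linear(self):
        assert pearson([1, 2, 3, 4], [2, 4, 6, 8]) == pytest.approx(1.0)

    def test_exact_anti_linear(self):
        assert pearson([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_matches_summation_formula(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x, y = rng.normal(size=50), rng.normal(size=50)
            assert pearson(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_bounded(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(xs)
        y = rng.normal(size=len(x))
        if np.ptp(x) == 0:
            return
        r = pearson(x, y)
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(pearson(y, x))


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        assert spearman([1, 2, 3, 4], [1, 4, 9, 16]) == pytest.approx(1.0)

    def test_decreasing_gives_minus_one(self):
        assert spearman([1, 2, 3, 4, 5], [25, 9, 4, 1, 0.5]) == pytest.approx(-1.0)

    def test_ties_equal_pearson_on_midranks(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
            y = rng.integers(0, 5, size=20).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            expected = pearson_oracle(midrank(x), midrank(y))
            assert spearman(x, y) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y), abs=1e-12)


class TestCorrelationPvalue:
    def test_null_correlation(self):
        t, p = correlation_pvalue(0.0, 20)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_t_formula_exact(self):
        for r in [0.1, 0.3, 0.6, 0.9]:
            for n in [10, 20, 50]:
                t, _ = correlation_pvalue(r, n)
                assert t == pytest.approx(r * math.sqrt((n - 2) / (1 - r * r)), rel=1e-14)

    def test_p_monotone_decreasing_in_abs_r(self):
        pvals = [correlation_pvalue(r, 10)[1] for r in [0.0, 0.3, 0.6, 0.9, 0.99999]]
        assert all(a > b for a, b in zip(pvals, pvals[1:]))

    def test_perfect_correlation_clamped_not_fatal(self):
        t, p = correlation_pvalue(1.0, 10)
        assert np.isfinite(t) and p < 1e-10

    def test_small_n_rejected(self):
        with pytest.raises(InputError):
            correlation_pvalue(0.5, 3)


class TestBuildBaseNetwork:
    def _planted_matrix(self, rng, n=50):
        g1 = rng.normal(size=n)
        g2 = g1 + rng.normal(scale=0.05, size=n)  # near-perfect partner
        g3 = rng.normal(size=n)  # independent
        return make_matrix(np.vstack([g1, g2, g3]) + 8.0)

    def test_correlated_pair_found_independent_gene_absent(self):
        rng = np.random.default_rng(17)
        expr = self._planted_matrix(rng)
        cls = make_class_map(46, 4)
        net = build_base_network(expr, cls, "classA")
        pairs = set(zip(net.edges["gene_a"], net.edges["gene_b"]))
        assert ("G1", "G2") in pairs
        assert ("G1", "G3") not in pairs and ("G2", "G3") not in pairs
        # direct pairwise oracle agreement
        row = net.edges.set_index(["gene_a", "gene_b"]).loc[("G1", "G2")]
        sub = expr.data[cls.samples("classA")]
        assert row["r"] == pytest.approx(
            pearson(sub.loc["G1"], sub.loc["G2"]), abs=1e-12
        )

    def test_threshold_is_strict(self):
        # numerically perfect correlation clips to r = 1.0; |r| > 1.0 fails
        rng = np.random.default_rng(2)
        base = rng.normal(size=8)
        expr = make_matrix(np.vstack([base, 2 * base + 1]))
        cls = make_class_map(4, 4)
        net = build_base_network(expr, cls, "classA", base_r=1.0)
        assert len(net) == 0

    def test_gene_order_independence(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=(12, 30))
        values[1] = values[0] + rng.normal(scale=0.1, size=30)
        expr = make_matrix(values)
        perm = rng.permutation(12)
        shuffled = make_matrix(values[perm], row_ids=[f"G{i + 1}" for i in perm])
        cls = make_class_map(26, 4)
        net_a = build_base_network(expr, cls, "classA")
        net_b = build_base_network(shuffled, cls, "classA")
        assert net_a.edges.equals(net_b.edges)

    def test_zero_variance_gene_skipped_and_logged(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(3, 20))
        values[2] = 7.0
        expr = make_matrix(values)
        cls = make_class_map(16, 4)
        net = build_base_network(expr, cls, "classA")
        assert net.skipped_genes == ["G3"]
        assert "G3" not in net.nodes


class TestPairwiseCorrelation:
    def test_matches_direct_pairwise_loop(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(20, 40))
        corr = pairwise_correlation(values)
        for i in range(20):
            for j in range(i + 1, 20):
                assert corr[i, j] == pytest.approx(
                    pearson(values[i], values[j]), abs=1e-10
                )

    def test_worker_count_does_not_change_result(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(600, 25))
        serial = pairwise_correlation(values, n_workers=1)
        threaded = pairwise_correlation(values, n_workers=4)
        assert np.array_equal(serial, threaded)

    def test_spearman_mode_equals_rank_pearson(self):
        rng = np.random.default_rng(12)
        values = rng.integers(0, 6, size=(8, 25)).astype(float)
        corr = pairwise_correlation(values, method="spearman")
        for i in range(8):
            for j in range(i + 1, 8):
                if np.ptp(values[i]) and np.ptp(values[j]):
                    assert corr[i, j] == pytest.approx(
                        spearman(values[i], values[j]), abs=1e-12
                    )
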