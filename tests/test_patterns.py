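"""Contribution vectors, pattern correlations, hypergeometric overlap."""

import numpy as np
import pytest

from neurocpm.atlas import Atlas
from neurocpm.edges import EdgeMask, n_edges
from neurocpm.patterns import (
    compare_contributions,
    contribution,
    cross_compare,
    overlap_test,
)
from neurocpm.validation import (
    hypergeom_tail_bruteforce,
    hypergeom_tail_exact,
)


@pytest.fixture
def atlas10():
    return Atlas.uniform(10, region_labels=("prefrontal", "motor_strip",
                                            "cerebellum", "limbic"))


class TestContribution:
    def test_single_between_region_edge(self, atlas10):
        # nodes 0 and 9 are in different regions
        mask = EdgeMask.from_pairs(10, pos_pairs=[(0, 9)])
        node = contribution(mask, "pos", atlas10, "node")
        assert node.values[0] == 1.0 and node.values[9] == 1.0
        assert node.values.sum() == pytest.approx(2.0)
        region = contribution(mask, "pos", atlas10, "region")
        assert sorted(region.values) == [0.0, 0.0, 1.0, 1.0]

    def test_single_within_region_edge(self, atlas10):
        mask = EdgeMask.from_pairs(10, pos_pairs=[(0, 1)])  # both prefrontal
        region = contribution(mask, "pos", atlas10, "region")
        assert region.values[list(region.labels).index("prefrontal")] == 1.0
        assert region.values.sum() == pytest.approx(1.0)

    def test_star_network_hub(self, atlas10):
        mask = EdgeMask.from_pairs(10, neg_pairs=[(4, 0), (4, 1), (4, 2), (4, 3)])
        node = contribution(mask, "neg", atlas10, "node")
        assert node.values[4] == 1.0
        for leaf in (0, 1, 2, 3):
            assert node.values[leaf] == 0.25

    def test_node_level_sums_to_two(self, atlas10, rng):
        edges = rng.choice(n_edges(10), size=12, replace=False)
        mask = EdgeMask(n_nodes=10, pos_edges=edges)
        c = contribution(mask, "pos", atlas10, "node")
        assert c.values.sum() == pytest.approx(2.0)

    def test_region_level_sum_between_one_and_two(self, atlas10, rng):
        edges = rng.choice(n_edges(10), size=15, replace=False)
        mask = EdgeMask(n_nodes=10, neg_edges=edges)
        c = contribution(mask, "neg", atlas10, "region")
        assert 1.0 <= c.values.sum() <= 2.0

    def test_empty_network_rejected(self, atlas10):
        with pytest.raises(ValueError, match="empty"):
            contribution(EdgeMask(n_nodes=10), "pos", atlas10)


class TestCompareContributions:
    def test_identical_vectors_give_one(self, atlas10, rng):
        edges = rng.choice(n_edges(10), size=8, replace=False)
        mask = EdgeMask(n_nodes=10, pos_edges=edges)
        c = contribution(mask, "pos", atlas10, "node")
        r, p = compare_contributions(c, c)
        assert r == pytest.approx(1.0)

    def test_disjoint_one_hot_closed_form(self, atlas10):
        """Two one-hot region vectors of length L correlate at -1/(L-1)."""
        a = EdgeMask.from_pairs(10, pos_pairs=[(0, 1)])    # within prefrontal
        b = EdgeMask.from_pairs(10, pos_pairs=[(3, 4)])    # within motor strip
        ca = contribution(a, "pos", atlas10, "region")
        cb = contribution(b, "pos", atlas10, "region")
        r, _ = compare_contributions(ca, cb)
        L = len(ca.labels)
        assert r == pytest.approx(-1.0 / (L - 1), abs=1e-12)

    def test_independent_networks_centered_near_zero(self, atlas10):
        rng = np.random.default_rng(17)
        rs = []
        for _ in range(60):
            ea, eb = (rng.choice(n_edges(10), size=10, replace=False)
                      for _ in range(2))
            ca = contribution(EdgeMask(n_nodes=10, pos_edges=ea), "pos",
                              atlas10, "node")
            cb = contribution(EdgeMask(n_nodes=10, pos_edges=eb), "pos",
                              atlas10, "node")
            rs.append(compare_contributions(ca, cb)[0])
        assert abs(np.mean(rs)) < 0.15

    def test_zero_variance_flagged(self):
        atlas = Atlas.uniform(4, region_labels=("prefrontal",))
        full = EdgeMask(n_nodes=4, pos_edges=np.arange(n_edges(4)))
        c = contribution(full, "pos", atlas, "node")  # all nodes equal share
        r, p = compare_contributions(c, c)
        assert np.isnan(r) and np.isnan(p)

    def test_mismatched_levels_rejected(self, atlas10):
        mask = EdgeMask.from_pairs(10, pos_pairs=[(0, 1)])
        a = contribution(mask, "pos", atlas10, "node")
        b = contribution(mask, "pos", atlas10, "region")
        with pytest.raises(ValueError):
            compare_contributions(a, b)


class TestOverlap:
    def test_disjoint_sets(self):
        res = overlap_test(np.array([0, 1, 2]), np.array([3, 4]), n_nodes=6)
        assert res.x == 0
        assert res.p == pytest.approx(float(hypergeom_tail_exact(0, 15, 3, 2)))
        assert res.p < 1

    def test_identical_sets_give_zero_under_printed_convention(self):
        """x = K = n maximizes the CDF, so p = 1 - CDF(x) = 0."""
        edges = np.array([0, 2, 5])
        res = overlap_test(edges, edges, n_nodes=6)
        assert res.x == 3
        assert res.p == 0.0
        inc = overlap_test(edges, edges, n_nodes=6, inclusive=True)
        assert inc.p > 0

    def test_small_case_matches_draw_enumeration(self):
        # M = 10, K = 3, n = 4, x = 2
        a = np.array([0, 1, 2])
        b = np.array([0, 1, 5, 7])
        res = overlap_test(a, b, n_nodes=5, m_total=10)
        assert res.x == 2
        assert res.p == pytest.approx(float(hypergeom_tail_bruteforce(2, 10, 3, 4)))

    def test_symmetric_in_arguments(self, rng):
        a = rng.choice(50, size=8, replace=False)
        b = rng.choice(50, size=12, replace=False)
        ra = overlap_test(a, b, n_nodes=12, m_total=50)
        rb = overlap_test(b, a, n_nodes=12, m_total=50)
        assert ra.x == rb.x

    def test_random_overlap_near_expectation(self):
        """Overlap of independent draws concentrates around K n / M."""
        rng = np.random.default_rng(23)
        m, k, n = 300, 40, 60
        xs = [overlap_test(rng.choice(m, k, replace=False),
                           rng.choice(m, n, replace=False),
                           n_nodes=30, m_total=m).x
              for _ in range(100)]
        assert np.mean(xs) == pytest.approx(k * n / m, abs=1.0)


class TestCrossCompare:
    def make_connectome(self, seed, atlas):
        rng = np.random.default_rng(seed)
        edges = rng.choice(n_edges(atlas.n_nodes), size=16, replace=False)
        return EdgeMask(n_nodes=atlas.n_nodes, pos_edges=edges[:8],
                        neg_edges=edges[8:])

    def test_identical_connectomes_diagonal(self, atlas10):
        a = self.make_connectome(31, atlas10)
        table = cross_compare(a, a, atlas10)
        assert len(table) == 4
        diag = table[(table.network_a == table.network_b)]
        np.testing.assert_allclose(diag["node_r"], 1.0)
        np.testing.assert_allclose(diag["region_r"], 1.0)
        np.testing.assert_array_equal(diag["overlap_x"], 8)
        np.testing.assert_array_equal(diag["overlap_p"], 0.0)

    def test_one_sign_connectome_skips_two_comparisons(self, atlas10):
        a = self.make_connectome(32, atlas10)
        b = EdgeMask(n_nodes=10, pos_edges=np.array([0, 1, 2]))
        table = cross_compare(a, b, atlas10)
        assert table["skipped"].sum() == 2
        assert len(table) == 4
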