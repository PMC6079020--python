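"""Diversity and permutation statistics, checked against closed forms,
exhaustive enumeration and scikit-bio."""

import itertools
import math

import numpy as np
import pytest

import _oracles
from redsnow.stats import (
    DistanceMatrix, bray_curtis, bray_curtis_matrix, haversine_km, mantel,
    pairwise_permanova, permanova, shannon, upgma, upgma_newick,
)


class TestShannon:
    def test_uniform_counts(self):
        assert shannon([10, 10, 10, 10]) == pytest.approx(math.log(4))

    def test_single_taxon(self):
        assert shannon([7]) == 0.0

    def test_frozen_hand_value(self):
        # -sum p ln p for p = (1/6, 2/6, 3/6), evaluated by hand once
        assert shannon([1, 2, 3]) == pytest.approx(1.011404, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([5, 0], [0, 9]) == 1.0

    def test_hand_value(self):
        assert bray_curtis((2, 1), (1, 1)) == pytest.approx(0.2)

    def test_bounds_and_symmetry(self, rng):
        for _ in range(30):
            x = rng.integers(0, 20, size=6)
            y = rng.integers(0, 20, size=6)
            if x.sum() + y.sum() == 0:
                continue
            d = bray_curtis(x, y)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(y, x))

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        nwk = upgma_newick(dm)
        assert nwk == "(A:0.2,B:0.2);"

    def test_three_leaf_hand_agglomeration(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        dm = DistanceMatrix(["A", "B", "C"], d)
        nwk = upgma_newick(dm)
        assert nwk == "((A:0.1,B:0.1):0.2,C:0.3);"

    def test_ultrametric(self, rng):
        import skbio
        n = 6
        d = rng.random((n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = [f"L{i}" for i in range(n)]
        tree = skbio.TreeNode.read([upgma_newick(DistanceMatrix(labels, d))])
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert max(depths.values()) - min(depths.values()) < 1e-8

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))


def two_group_distance(n_per=3, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    pts = np.concatenate([rng.normal(0, 0.1, (n_per, 2)),
                          rng.normal(sep, 0.1, (n_per, 2))])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(2 * n_per)]
    return DistanceMatrix(labels, d), ["g1"] * n_per + ["g2"] * n_per


class TestPermanova:
    def test_exhaustive_small_n_minimal_p(self):
        dm, groups = two_group_distance()
        res = permanova(dm, groups, exhaustive=True)
        # 72 of the 720 label permutations preserve the two tight groups
        assert res.p_value == pytest.approx(72 / 720)
        assert res.statistic == pytest.approx(
            _oracles.pseudo_f_direct(dm.d, groups))

    def test_exhaustive_matches_manual_enumeration(self):
        rng = np.random.default_rng(5)
        d = rng.random((5, 5)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        dm = DistanceMatrix(list("abcde"), d)
        groups = ["x", "x", "y", "y", "y"]
        res = permanova(dm, groups, exhaustive=True)
        obs = _oracles.pseudo_f_direct(d, groups)
        stats = []
        for p in itertools.permutations(range(5)):
            g = [groups[i] for i in p]
            stats.append(_oracles.pseudo_f_direct(d, g))
        expect = sum(1 for s in stats if s >= obs - 1e-12) / len(stats)
        assert res.p_value == pytest.approx(expect)

    def test_row_order_invariance(self):
        dm, groups = two_group_distance()
        perm = [3, 0, 5, 1, 4, 2]
        d2 = dm.d[np.ix_(perm, perm)]
        g2 = [groups[i] for i in perm]
        r1 = permanova(dm, groups, n_perm=49, seed=1)
        r2 = permanova(DistanceMatrix([dm.labels[i] for i in perm], d2), g2,
                       n_perm=49, seed=1)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_scikit_bio_statistic(self):
        import skbio
        dm, groups = two_group_distance(n_per=4, sep=2.0, seed=3)
        ours = permanova(dm, groups, n_perm=9, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, dm.labels), groups, permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"])

    def test_single_group_rejected(self):
        dm, _ = two_group_distance()
        with pytest.raises(ValueError):
            permanova(dm, ["g"] * 6)

    def test_pairwise_contrasts_and_bonferroni(self):
        rng = np.random.default_rng(9)
        pts = np.concatenate([rng.normal(i * 5, 0.2, (3, 2)) for i in range(3)])
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(9)], d)
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        plain = pairwise_permanova(dm, groups, n_perm=99, seed=0)
        assert set(plain) == {("a", "b"), ("a", "c"), ("b", "c")}
        corrected = pairwise_permanova(dm, groups, n_perm=99, seed=0,
                                       bonferroni=True)
        for pair in plain:
            assert corrected[pair].p_value == pytest.approx(
                min(1.0, plain[pair].p_value * 3))


class TestMantel:
    def _dm(self, seed, n=5):
        rng = np.random.default_rng(seed)
        d = rng.random((n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_perfect_linear_relation(self):
        d1 = self._dm(1)
        d2 = DistanceMatrix(d1.labels, 2 * d1.d)
        res = mantel(d1, d2, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_exhaustive_small_n_matches_oracle(self):
        d1 = self._dm(2, n=4)
        d2 = self._dm(3, n=4)
        res = mantel(d1, d2, exhaustive=True)
        obs = _oracles.mantel_r_direct(d1.d, d2.d)
        assert res.statistic == pytest.approx(obs)
        stats = []
        for p in itertools.permutations(range(4)):
            stats.append(_oracles.mantel_r_direct(d1.d, d2.d[np.ix_(p, p)]))
        expect = sum(1 for s in stats if s >= obs - 1e-12) / len(stats)
        assert res.p_value == pytest.approx(expect)

    def test_relabeling_invariance(self):
        d1 = self._dm(4)
        d2 = self._dm(5)
        perm = [2, 0, 4, 1, 3]
        r1 = mantel(d1, d2, n_perm=9, seed=0)
        d1p = DistanceMatrix([d1.labels[i] for i in perm], d1.d[np.ix_(perm, perm)])
        d2p = DistanceMatrix([d2.labels[i] for i in perm], d2.d[np.ix_(perm, perm)])
        r2 = mantel(d1p, d2p, n_perm=9, seed=0)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_scikit_bio_r(self):
        import skbio
        d1 = self._dm(6, n=6)
        d2 = self._dm(7, n=6)
        ours = mantel(d1, d2, n_perm=9, seed=0)
        r, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(d1.d, d1.labels),
            skbio.DistanceMatrix(d2.d, d2.labels),
            permutations=9)
        assert ours.statistic == pytest.approx(r)

    def test_label_mismatch_rejected(self):
        d1 = self._dm(8)
        d2 = DistanceMatrix([f"x{i}" for i in range(5)], d1.d)
        with pytest.raises(ValueError):
            mantel(d1, d2)


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km(45.0, 10.0, 45.0, 10.0) == 0.0

    def test_antipodal_on_equator(self):
        assert haversine_km(0, 0, 0, 180) == pytest.approx(math.pi * 6371, rel=1e-6)

    def test_symmetry(self):
        assert haversine_km(78.9, 11.9, -69.2, 39.7) == pytest.approx(
            haversine_km(-69.2, 39.7, 78.9, 11.9))

    def test_range_validation(self):
        with pytest.raises(ValueError):
            haversine_km(91, 0, 0, 0)


def test_bray_curtis_matrix_symmetric_zero_diagonal(rng):
    counts = rng.integers(1, 30, size=(5, 8))
    dm = bray_curtis_matrix(counts, [f"s{i}" for i in range(5)])
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0)
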