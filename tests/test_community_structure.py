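import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
import skbio.stats.distance as sksd

from phyllocore import community_structure as cs
from phyllocore.io_prep import AbundanceTable

from conftest import make_relative


def _dm_from_points(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestBrayCurtis:
    def test_identity_and_disjoint_supports(self):
        tab = AbundanceTable(
            pd.DataFrame(
                [[1, 2, 0], [1, 2, 0], [0, 0, 5]],
                index=["a", "b", "c"],
                columns=["x", "y", "z"],
                dtype=float,
            )
        )
        d = cs.bray_curtis(tab)
        assert d["a", "b"] == 0.0
        assert d["a", "c"] == 1.0

    def test_hand_computation(self):
        tab = AbundanceTable(
            pd.DataFrame(
                [[1, 1, 0], [0, 1, 1]], index=["a", "b"], columns=["x", "y", "z"], dtype=float
            )
        )
        assert cs.bray_curtis(tab)["a", "b"] == pytest.approx(0.5)

    def test_two_all_zero_samples_rejected(self):
        tab = AbundanceTable(
            pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"], dtype=float)
        )
        with pytest.raises(ValueError, match="all-zero"):
            cs.bray_curtis(tab)


class TestNMDS:
    def test_embeddable_distances_reach_near_zero_stress(self):
        rng = np.random.default_rng(1)
        dm = _dm_from_points(rng.normal(size=(12, 2)))
        res = cs.nmds(dm, k=2, n_restarts=5, seed=2)
        assert res.stress < 0.01

    def test_stress_sequence_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 6))
        dm = DistanceMatrix(squareform(pdist(X, "braycurtis")), ids=[f"s{i}" for i in range(10)])
        res = cs.nmds(dm, k=2, n_restarts=5, seed=4)
        assert np.all(np.diff(res.stress_sequence) <= 1e-12)

    def test_square_configuration_rank_agreement(self):
        dm = _dm_from_points([[0, 0], [1, 0], [1, 1], [0, 1]])
        res = cs.nmds(dm, k=2, n_restarts=10, seed=5)
        fitted = pdist(res.coordinates.to_numpy())
        orig = squareform(dm.data)
        # every strictly ordered input pair must stay ordered in the solution
        # (the square's tied side/diagonal lengths are free to break ties)
        for i in range(len(orig)):
            for j in range(len(orig)):
                if orig[i] < orig[j]:
                    assert fitted[i] < fitted[j]

    def test_coordinates_centered(self):
        dm = _dm_from_points(np.random.default_rng(6).normal(size=(8, 2)) + 5.0)
        res = cs.nmds(dm, k=2, n_restarts=3, seed=7)
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_too_few_samples_rejected(self):
        dm = _dm_from_points([[0, 0], [1, 1], [2, 0]])
        with pytest.raises(ValueError):
            cs.nmds(dm, k=2, n_restarts=2, seed=0)


class TestPermanova:
    def _toy(self, seed=2, n=6):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 4))
        return DistanceMatrix(
            squareform(pdist(X, "braycurtis")), ids=[f"s{i}" for i in range(n)]
        )

    def test_matches_exhaustive_enumeration(self):
        d = self._toy()
        groups = np.array(["g1"] * 3 + ["g2"] * 3)
        G = cs._gower_center(d.data)
        f_obs, _ = cs._permanova_f(G, groups)
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            fp, _ = cs._permanova_f(G, groups[list(perm)])
            hits += fp >= f_obs - 1e-12
            total += 1
        res = cs.permanova(d, groups, n_perms=999, seed=5)
        assert abs(res.p - hits / total) < 0.02

    def test_statistic_agrees_with_skbio(self):
        d = self._toy(seed=9, n=12)
        groups = np.repeat(["a", "b", "c"], 4)
        res = cs.permanova(d, groups, n_perms=99, seed=1)
        sk = sksd.permanova(d, grouping=groups, permutations=99)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_disjoint_groups_reach_minimum_p(self):
        # 10 + 10 samples: the chance a random permutation recreates the exact
        # split (tying the observed F) is ~1e-5, so p attains its minimum
        tab = make_relative(
            np.block(
                [
                    [np.random.default_rng(0).random((10, 4)), np.zeros((10, 4))],
                    [np.zeros((10, 4)), np.random.default_rng(1).random((10, 4))],
                ]
            )
        )
        d = cs.bray_curtis(tab)
        groups = np.array(["x"] * 10 + ["y"] * 10)
        res = cs.permanova(d, groups, n_perms=999, seed=3)
        assert res.p == pytest.approx(1 / 1000)

    def test_r2_is_sample_order_invariant(self):
        d = self._toy(seed=4, n=10)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res1 = cs.permanova(d, groups, n_perms=49, seed=0)
        perm = np.random.default_rng(5).permutation(10)
        ids = [d.ids[i] for i in perm]
        res2 = cs.permanova(d.filter(ids), groups[perm], n_perms=49, seed=0)
        assert res1.r2 == pytest.approx(res2.r2)

    def test_singleton_group_rejected(self):
        d = self._toy()
        with pytest.raises(ValueError, match="single"):
            cs.permanova(d, np.array(["a"] * 5 + ["b"]), n_perms=9, seed=0)

    def test_pairwise_holm_not_below_raw(self):
        d = self._toy(seed=11, n=12)
        groups = np.repeat(["a", "b", "c"], 4)
        pw = cs.pairwise_permanova(d, groups, n_perms=99, seed=2)
        assert (pw["p_adj"] >= pw["p"] - 1e-12).all()


class TestBetaDispersion:
    def test_identical_samples_zero_dispersion(self):
        pts = np.vstack([np.zeros((3, 2)), np.ones((3, 2))])
        d = _dm_from_points(pts)
        disp, _ = cs.beta_dispersion(d, ["a"] * 3 + ["b"] * 3)
        assert disp["a"] == pytest.approx(0.0, abs=1e-9)

    def test_doubling_spread_doubles_dispersion(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(8, 2))
        d1 = _dm_from_points(base)
        d2 = _dm_from_points(2 * base)
        g = ["a"] * 8
        disp1, _ = cs.beta_dispersion(d1, g)
        disp2, _ = cs.beta_dispersion(d2, g)
        assert disp2["a"] == pytest.approx(2 * disp1["a"], rel=1e-9)

    def test_pair_distances_symmetric(self):
        d = _dm_from_points([[0, 0], [2, 0], [5, 5], [6, 5]])
        _, dist = cs.beta_dispersion(d, ["a", "a", "b", "b"])
        assert dist.iloc[0] == pytest.approx(dist.iloc[1])
        assert dist.iloc[0] == pytest.approx(1.0)  # half the pair distance


class TestCentroidDistance:
    def test_identical_groups_zero(self):
        pts = np.tile(np.random.default_rng(0).normal(size=(3, 2)), (2, 1))
        d = _dm_from_points(pts)
        assert cs.centroid_distance(d, ["a"] * 3 + ["b"] * 3, ("a", "b")) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_planted_separation_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(0, 0.1, size=(10, 2)) + np.array([3.0, 0.0])
        d = _dm_from_points(np.vstack([a, b]))
        est = cs.centroid_distance(d, ["a"] * 10 + ["b"] * 10, ("a", "b"))
        assert est == pytest.approx(3.0, abs=0.15)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(8, 3))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        d = _dm_from_points(pts)
        ref = cs.centroid_distance(d, groups, ("a", "b"))
        perm = rng.permutation(8)
        d2 = d.filter([d.ids[i] for i in perm])
        assert cs.centroid_distance(d2, groups[perm], ("a", "b")) == pytest.approx(ref)


class TestMantel:
    def _pair(self, seed=2):
        rng = np.random.default_rng(seed)
        X = rng.random((6, 4))
        Y = np.abs(X + rng.normal(0, 0.2, X.shape))
        ids = list("abcdef")
        d1 = DistanceMatrix(squareform(pdist(X, "braycurtis")), ids=ids)
        d2 = DistanceMatrix(squareform(pdist(Y, "braycurtis")), ids=ids)
        return d1, d2

    def test_identity_and_affine_invariance(self):
        d1, _ = self._pair()
        r, _ = cs.mantel(d1, d1, n_perms=99, seed=0)
        assert r == pytest.approx(1.0)
        affine = DistanceMatrix(0.5 * d1.data + 0.1 * (1 - np.eye(6)), ids=list(d1.ids))
        r2, _ = cs.mantel(d1, affine, n_perms=99, seed=0)
        assert r2 == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        d1, d2 = self._pair()
        x = squareform(d1.data)
        r_obs = np.corrcoef(x, squareform(d2.data))[0, 1]
        hits = total = 0
        for perm in itertools.permutations(range(6)):
            rp = np.corrcoef(x, squareform(d2.data[np.ix_(perm, perm)]))[0, 1]
            hits += rp >= r_obs
            total += 1
        r, p = cs.mantel(d1, d2, n_perms=999, seed=4)
        assert r == pytest.approx(r_obs)
        assert abs(p - hits / total) < 0.02

    def test_agrees_with_skbio_statistic(self):
        d1, d2 = self._pair(seed=8)
        r, _ = cs.mantel(d1, d2, n_perms=99, seed=1)
        sk_r, _, _ = sksd.mantel(d1, d2, permutations=0, alternative="greater")
        assert r == pytest.approx(sk_r, rel=1e-9)

    def test_mismatched_samples_rejected(self):
        d1, d2 = self._pair()
        with pytest.raises(ValueError, match="same samples"):
            cs.mantel(d1, d2.filter(list("abcdfe")), n_perms=9, seed=0)
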