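from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from qmpflow import structure
from qmpflow.tables import FeatureTable


class TestShannon:
    def test_uniform_is_log_richness(self):
        assert structure.shannon(np.ones(8)) == pytest.approx(np.log(8))

    def test_single_taxon_zero(self):
        assert structure.shannon([1, 0, 0]) == 0.0

    def test_hand_computed_value(self):
        # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25) = 1.0397
        assert structure.shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            structure.shannon([0.0, 0.0])

    def test_base_conversion(self):
        assert structure.shannon(np.ones(8), base=2) == pytest.approx(3.0)


class TestBrayCurtis:
    def test_identical_zero(self):
        assert structure.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_one(self):
        assert structure.bray_curtis([1, 0, 2], [0, 3, 0]) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert structure.bray_curtis([1, 2, 3], [3, 2, 1]) == pytest.approx(1 / 3)

    def test_double_zero_undefined(self):
        with pytest.raises(ValueError):
            structure.bray_curtis([0, 0], [0, 0])


def _table_from(matrix, meta):
    idx = [f"s{i}" for i in range(len(matrix))]
    return FeatureTable(
        pd.DataFrame(matrix, index=idx),
        pd.DataFrame(meta, index=idx),
    )


class TestAdjacentTime:
    def test_identical_communities_give_zero(self):
        t = _table_from(
            [[1, 2]] * 4,
            {"segment": ["cecum"] * 4, "dph": [1, 1, 4, 4], "bird": list("abab")},
        )
        res = structure.adjacent_time_dissimilarity(t, "cecum")
        assert (res.bc == 0).all()

    def test_pair_counting(self):
        rng = np.random.default_rng(0)
        n = 10
        t = _table_from(
            rng.random((2 * n, 5)) + 0.1,
            {"segment": ["cecum"] * 2 * n, "dph": [1] * n + [4] * n,
             "bird": [f"b{i}" for i in range(n)] * 2},
        )
        res = structure.adjacent_time_dissimilarity(t, "cecum")
        assert len(res) == n * n
        assert set(res.interval) == {"1-4"}

    def test_planted_shift_has_highest_median(self):
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(20), size=1)[0]
        other = rng.dirichlet(np.ones(20), size=1)[0]
        rows, dph = [], []
        for day in (1, 4, 7, 14):
            centre = other if day == 1 else base  # big shift between 1 and 4
            for _ in range(5):
                rows.append(centre + rng.normal(0, 0.002, 20).clip(-0.001))
            dph.extend([day] * 5)
        t = _table_from(
            np.abs(rows), {"segment": ["cecum"] * len(rows), "dph": dph,
                           "bird": [f"b{i%5}" for i in range(len(rows))]},
        )
        res = structure.adjacent_time_dissimilarity(t, "cecum")
        med = res.groupby("interval", sort=False).bc.median()
        assert med.idxmax() == "1-4"


class TestPcoa:
    def test_three_equidistant_points(self):
        dm = pd.DataFrame(1.0 - np.eye(3))
        coords, eig = structure.pcoa(dm)
        pos = np.sort(eig[eig > 1e-9])
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1], rel=1e-9)

    def test_planar_distances_recovered(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        dm = pd.DataFrame(squareform(pdist(pts)))
        coords, _ = structure.pcoa(dm)
        rec = squareform(pdist(coords.to_numpy()[:, :2]))
        np.testing.assert_allclose(rec, dm.to_numpy(), atol=1e-8)

    def test_duplicate_sample_coincident(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        dm = pd.DataFrame(squareform(pdist(pts)))
        coords, _ = structure.pcoa(dm)
        np.testing.assert_allclose(
            coords.iloc[1].to_numpy(), coords.iloc[2].to_numpy(), atol=1e-9
        )

    def test_asymmetric_rejected(self):
        dm = pd.DataFrame([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError):
            structure.pcoa(dm)


def _exact_permanova_p(dm, labels):
    """Brute-force permutation oracle: full enumeration of distinct
    label arrangements."""
    from qmpflow.structure import permanova

    obs = permanova(dm, labels, n_perm=0).pseudo_f

    d2 = np.asarray(dm) ** 2
    lab = np.asarray(labels)
    groups = np.unique(lab)
    n = len(lab)

    def stat(arrangement):
        arrangement = np.asarray(arrangement)
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in groups:
            idx = np.flatnonzero(arrangement == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (len(groups) - 1)) / (ss_within / (n - len(groups)))

    perms = set(permutations(lab))
    count = sum(1 for p in perms if stat(p) >= obs - 1e-12)
    return count / len(perms)


class TestPermanova:
    def _dm(self, pts):
        return pd.DataFrame(squareform(pdist(pts)))

    def test_identical_group_compositions_null(self):
        # both groups contain the same four communities -> no group effect
        base = np.random.default_rng(0).normal(size=(4, 3))
        dm = self._dm(np.vstack([base, base]))
        labels = pd.Series(list("aaaabbbb"))
        res = structure.permanova(dm, labels, n_perm=199, seed=0)
        assert res.r_squared < 0.05 and res.p_value > 0.5

    def test_exact_enumeration_oracle_small_n(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        dm = self._dm(pts)
        labels = pd.Series(list("aaabbb"))
        exact = _exact_permanova_p(dm, labels)
        res = structure.permanova(dm, labels, n_perm=9999, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_perfect_separation_minimal_p(self):
        # groups large enough that no permutation recreates the partition
        pts = np.vstack([np.zeros((8, 2)), np.ones((8, 2)) * 100])
        pts += np.random.default_rng(0).normal(0, 0.01, (16, 2))
        dm = self._dm(pts)
        labels = pd.Series(list("a" * 8 + "b" * 8))
        res = structure.permanova(dm, labels, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_matches_skbio_pseudo_f(self):
        import skbio

        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        dm = self._dm(pts)
        labels = pd.Series(list("aaaabbbbcccc"))
        mine = structure.permanova(dm, labels, n_perm=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.to_numpy()), labels.to_numpy(), permutations=99
        )
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_pvalues_superuniform_under_shuffling(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(16, 3))
        dm = self._dm(pts)
        ps = []
        for rep in range(200):
            labels = pd.Series(rng.permutation(list("aaaaaaaabbbbbbbb")))
            ps.append(structure.permanova(dm, labels, n_perm=99, seed=rep).p_value)
        frac = np.mean(np.array(ps) <= 0.05)
        assert 0.0 <= frac <= 0.10

    def test_single_group_rejected(self):
        dm = self._dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValueError):
            structure.permanova(dm, pd.Series(list("aaaa")), n_perm=9)


class TestVariancePartition:
    def test_orthogonal_balanced_factors_r2_sum_below_one(self):
        rng = np.random.default_rng(5)
        f1 = np.repeat(["x", "y"], 8)
        f2 = np.tile(np.repeat(["u", "v"], 4), 2)
        pts = rng.normal(size=(16, 4))
        pts[f1 == "x"] += 0.5
        pts[f2 == "u", 1] += 0.5
        dm = pd.DataFrame(squareform(pdist(pts)))
        meta = pd.DataFrame({"f1": f1, "f2": f2})
        part = structure.variance_partition(dm, meta, ["f1", "f2"], n_perm=49)
        assert part.r_squared.sum() <= 1.0 + 1e-9


class TestProtest:
    def test_rotated_scaled_copy_perfect(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b = 3.0 * a @ rot + 5.0
        res = structure.protest(a, b, n_perm=99, seed=0)
        assert res.m12 == pytest.approx(1.0, abs=1e-9)
        assert np.max(res.residuals) < 1e-9

    def test_mirror_image_same_as_rotation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(15, 2))
        b_rot = a @ np.array([[0.0, -1], [1, 0]])
        b_mir = a * np.array([1.0, -1.0])  # reflection
        m_rot = structure.protest(a, b_rot, n_perm=49, seed=0).m12
        m_mir = structure.protest(a, b_mir, n_perm=49, seed=0).m12
        assert m_rot == pytest.approx(m_mir, abs=1e-9) == pytest.approx(1.0, abs=1e-9)

    def test_independent_configurations_not_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(20):
            a = rng.normal(size=(50, 2))
            b = rng.normal(size=(50, 2))
            if structure.protest(a, b, n_perm=99, seed=rep).p_value > 0.05:
                hits += 1
        assert hits >= 16  # >= 90% nominal, binomial slack at 20 reps

    def test_m12_symmetric(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(12, 2)), rng.normal(size=(12, 2))
        m_ab = structure.protest(a, b, n_perm=9, seed=0).m12
        m_ba = structure.protest(b, a, n_perm=9, seed=0).m12
        assert m_ab == pytest.approx(m_ba, abs=1e-8)
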