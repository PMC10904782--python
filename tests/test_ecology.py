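"""Coverage normalization, occupancy partitions, Bray-Curtis, PCoA, PERMANOVA."""

import numpy as np
import pandas as pd
import pytest

from vamp.ecology import (
    bray_curtis,
    normalize_coverage,
    partition_presence,
    pcoa,
    permanova,
    round_half_up,
)


class TestNormalizeCoverage:
    def test_per_gigabase_arithmetic(self):
        depth = pd.DataFrame({"s1": [10.0, 0.0]}, index=["f1", "f2"])
        norm = normalize_coverage(depth, {"s1": 2e9})
        assert norm.loc["f1", "s1"] == pytest.approx(5.0)
        assert norm.loc["f2", "s1"] == 0.0

    def test_library_size_scales_inversely(self):
        depth = pd.DataFrame({"a": [8.0], "b": [8.0]}, index=["f"])
        norm = normalize_coverage(depth, {"a": 1e9, "b": 4e9})
        assert norm.loc["f", "a"] == pytest.approx(4 * norm.loc["f", "b"])

    def test_unknown_sample_rejected(self):
        depth = pd.DataFrame({"s1": [1.0]}, index=["f"])
        with pytest.raises(KeyError):
            normalize_coverage(depth, {"other": 1e9})

    def test_nonpositive_library_rejected(self):
        depth = pd.DataFrame({"s1": [1.0]}, index=["f"])
        with pytest.raises(ValueError):
            normalize_coverage(depth, {"s1": 0.0})


class TestPartitionPresence:
    def test_two_site_sharing_fraction(self):
        # 10 features: 2 in both sites, 4 unique to each site
        rng = np.random.default_rng(0)
        m = pd.DataFrame(0.0, index=[f"f{i}" for i in range(10)], columns=["m1", "m2", "s1", "s2"])
        groups = {"m1": "muddy", "m2": "muddy", "s1": "sandy", "s2": "sandy"}
        for f in ["f0", "f1"]:
            m.loc[f] = rng.uniform(1, 5, 4)
        for f in ["f2", "f3", "f4", "f5"]:
            m.loc[f, ["m1", "m2"]] = 1.0
        for f in ["f6", "f7", "f8", "f9"]:
            m.loc[f, ["s1", "s2"]] = 1.0
        part = partition_presence(m, groups, grouping="site")
        assert part.in_all_groups == 2 and part.in_one_group == 8
        assert part.pct_in_all == 20.0 and part.pct_in_one == 80.0

    def test_all_features_everywhere(self):
        m = pd.DataFrame(1.0, index=["f1", "f2"], columns=["a", "b"])
        part = partition_presence(m, {"a": "x", "b": "y"})
        assert part.in_one_group == 0 and part.in_all_groups == 2

    def test_counts_match_bruteforce_occupancy_scan(self):
        rng = np.random.default_rng(5)
        n_feat, samples = 200, ["a1", "a2", "b1", "b2", "c1"]
        groups = {"a1": "g1", "a2": "g1", "b1": "g2", "b2": "g2", "c1": "g3"}
        m = pd.DataFrame(
            rng.random((n_feat, 5)) * (rng.random((n_feat, 5)) < 0.4),
            index=[f"f{i}" for i in range(n_feat)],
            columns=samples,
        )
        part = partition_presence(m, groups)
        # brute-force per-feature scan
        in_all = in_one = present = 0
        for f in m.index:
            occ = {groups[s] for s in samples if m.loc[f, s] > 0}
            if occ:
                present += 1
                in_all += occ == {"g1", "g2", "g3"}
                in_one += len(occ) == 1
        assert (part.n_features, part.in_all_groups, part.in_one_group) == (present, in_all, in_one)

    def test_single_group_rejected(self):
        m = pd.DataFrame(1.0, index=["f"], columns=["a", "b"])
        with pytest.raises(ValueError):
            partition_presence(m, {"a": "x", "b": "x"})


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["f1", "f2"])
        assert bray_curtis(m).loc["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame({"a": [3.0, 0.0], "b": [0.0, 7.0]}, index=["f1", "f2"])
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # x=(1,2,0), y=(0,2,4): sum|dx| = 5, sum(x+y) = 9 -> 5/9
        m = pd.DataFrame({"x": [1.0, 2.0, 0.0], "y": [0.0, 2.0, 4.0]})
        assert bray_curtis(m).loc["x", "y"] == pytest.approx(5 / 9)

    def test_matches_scipy(self):
        from scipy.spatial.distance import braycurtis as scipy_bc

        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((20, 6)), columns=[f"s{i}" for i in range(6)])
        d = bray_curtis(m)
        for i in range(6):
            for j in range(6):
                expected = 0.0 if i == j else scipy_bc(m.iloc[:, i], m.iloc[:, j])
                assert d.iloc[i, j] == pytest.approx(expected)

    def test_all_zero_pair_warns_and_is_zero(self):
        m = pd.DataFrame({"a": [0.0], "b": [0.0]})
        with pytest.warns(UserWarning):
            d = bray_curtis(m)
        assert d.loc["a", "b"] == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame({"a": [-1.0], "b": [1.0]}))

    def test_range_invariant(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.exponential(size=(30, 8)))
        d = bray_curtis(m).to_numpy()
        assert ((d >= 0) & (d <= 1)).all()


class TestPcoa:
    def test_two_samples_forced_coordinates(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"])
        res = pcoa(d)
        assert sorted(np.abs(res.coordinates["PCo1"])) == pytest.approx([0.5, 0.5])

    def test_collinear_points_one_axis(self):
        pts = np.array([0.0, 1.0, 2.0, 5.0])
        d = pd.DataFrame(np.abs(pts[:, None] - pts[None, :]))
        res = pcoa(d)
        assert res.eigenvalues[0] == pytest.approx(np.sum((pts - pts.mean()) ** 2))
        if res.eigenvalues.size > 1:
            assert res.eigenvalues[1] < 1e-8 * res.eigenvalues[0]

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(7, 3))
        d = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1)))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()
        recon = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        assert np.allclose(recon, d.to_numpy(), atol=1e-8)

    def test_duplicate_samples_coincide(self):
        m = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = pcoa(pd.DataFrame(m))
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[1], atol=1e-9)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.random((25, 6)), columns=[f"s{i}" for i in range(6)])
        d = bray_curtis(m)
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        k = min(3, ours.eigenvalues.size)
        assert np.allclose(ours.eigenvalues[:k], theirs.eigvals.to_numpy()[:k], atol=1e-8)
        for ax in range(k):
            a = ours.coordinates.iloc[:, ax].to_numpy()
            b = theirs.samples.iloc[:, ax].to_numpy()
            assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)  # axes defined up to sign

    def test_asymmetric_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            pcoa(d)


def _two_group_distance(n_per_group=2, sep=True):
    """Distance matrix with identical rows per group; perfect separation."""
    n = 2 * n_per_group
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and (i < n_per_group) == (j < n_per_group):
                d[i, j] = 0.0 if sep else 1.0
    ids = [f"s{i}" for i in range(n)]
    labels = pd.Series(["g1"] * n_per_group + ["g2"] * n_per_group, index=ids)
    return pd.DataFrame(d, index=ids, columns=ids), labels


class TestPermanova:
    def test_exhaustive_two_plus_two_perfect_separation(self):
        # All 6 distinct label assignments; only the true split and its mirror
        # reach the maximal F, so the exhaustive p-value is exactly 1/3.
        d, labels = _two_group_distance(2)
        res = permanova(d, labels, n_permutations="exhaustive")
        assert res.p_value == pytest.approx(1 / 3)

    def test_exhaustive_matches_sampling_limit(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.random((15, 6)), columns=[f"s{i}" for i in range(6)])
        d = bray_curtis(m)
        labels = pd.Series(["a", "a", "a", "b", "b", "b"], index=d.index)
        exact = permanova(d, labels, n_permutations="exhaustive")
        approx = permanova(d, labels, n_permutations=9999, seed=1)
        assert abs(exact.p_value - approx.p_value) < 0.05

    def test_matches_skbio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.random((30, 8)), columns=[f"s{i}" for i in range(8)])
        d = bray_curtis(m)
        labels = ["a", "a", "a", "a", "b", "b", "b", "b"]
        ours = permanova(d, pd.Series(labels, index=d.index), n_permutations=99, seed=0)
        theirs = sk_permanova(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)), grouping=labels, permutations=99
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.random((12, 6)), columns=[f"s{i}" for i in range(6)])
        d = bray_curtis(m)
        labels = np.array(["a", "b", "a", "b", "a", "b"])
        f1 = permanova(d, pd.Series(labels, index=d.index), n_permutations=9, seed=0).pseudo_F
        perm = rng.permutation(6)
        d2 = d.iloc[perm, perm]
        f2 = permanova(d2, pd.Series(labels[perm], index=d2.index), n_permutations=9, seed=0).pseudo_F
        assert f1 == pytest.approx(f2)

    def test_p_value_floor(self):
        d, labels = _two_group_distance(3)
        res = permanova(d, labels, n_permutations=99, seed=0)
        assert res.p_value >= 1 / 100

    def test_single_group_rejected(self):
        d, _ = _two_group_distance(2)
        with pytest.raises(ValueError):
            permanova(d, pd.Series(["g"] * 4, index=d.index), seed=0)


def test_round_half_up_convention():
    assert round_half_up(4.15) == 4.2
    assert round_half_up(74.95) == 75.0
    assert round_half_up(4.1649 * 10) / 10 == pytest.approx(4.2, abs=0.05)
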