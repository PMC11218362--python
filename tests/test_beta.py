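import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from npgut import beta as nb
from npgut.synthetic import (EffectSpec, SyntheticDesign, generate_community,
                             planted_scenario)
from npgut.preprocess import to_relative_abundance

from oracles import bh_stepup_reject, bray_curtis_direct


def dm_from_points(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(d, index=ids, columns=ids)


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        ab = pd.DataFrame([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 4]],
                          index=list("xyz"))
        d = nb.bray_curtis(ab, transform="none")
        assert d.at["x", "y"] == 0.0
        assert d.at["x", "z"] == 1.0

    def test_direct_formula_example(self):
        ab = pd.DataFrame([[1, 1], [3, 1]], index=["u", "v"])
        d = nb.bray_curtis(ab, transform="none")
        assert d.at["u", "v"] == pytest.approx(2 / 6)
        assert d.at["u", "v"] == pytest.approx(bray_curtis_direct([1, 1], [3, 1]))

    def test_log1p_transform_applied_before_distance(self):
        ab = pd.DataFrame([[10, 0], [0, 10]], index=["u", "v"]).astype(float)
        d = nb.bray_curtis(ab, transform="log1p")
        assert d.at["u", "v"] == pytest.approx(
            bray_curtis_direct(np.log1p([10, 0]), np.log1p([0, 10])))

    def test_binary_data_equals_sorensen(self, rng):
        X = (rng.random((6, 20)) < 0.4).astype(float)
        X[X.sum(axis=1) == 0, 0] = 1
        d = nb.bray_curtis(pd.DataFrame(X), transform="none")
        for i, j in itertools.combinations(range(6), 2):
            a = np.sum((X[i] > 0) & (X[j] > 0))
            b = np.sum((X[i] > 0) & (X[j] == 0))
            c = np.sum((X[i] == 0) & (X[j] > 0))
            assert d.iloc[i, j] == pytest.approx((b + c) / (2 * a + b + c))

    def test_two_all_zero_samples_rejected(self):
        ab = pd.DataFrame([[0, 0], [0, 0], [1, 2]], index=list("abc"))
        with pytest.raises(ValueError, match="all-zero"):
            nb.bray_curtis(ab)


class TestRobustAitchison:
    def test_hand_computed_rclr(self):
        counts = pd.DataFrame([[1.0, np.e]], index=["s"])
        z = nb.rclr_transform(counts)
        assert np.allclose(z.loc["s"], [-0.5, 0.5])

    def test_identical_samples_distance_zero(self):
        counts = pd.DataFrame([[3, 0, 7], [3, 0, 7]], index=["a", "b"])
        assert nb.robust_aitchison(counts).at["a", "b"] == 0.0

    def test_zeros_stay_zero_in_transform(self):
        counts = pd.DataFrame([[0, 2, 8]], index=["s"])
        z = nb.rclr_transform(counts)
        assert z.iloc[0, 0] == 0.0
        assert z.iloc[0, 1:].sum() == pytest.approx(0.0)  # centered over nonzeros

    def test_metric_contract_on_random_fixtures(self, rng):
        for _ in range(100):
            counts = pd.DataFrame(rng.integers(0, 20, size=(4, 8)) + np.eye(4, 8, dtype=int))
            d = nb.robust_aitchison(counts).to_numpy()
            assert np.allclose(d, d.T) and (d >= 0).all()
            for i, j, k in itertools.permutations(range(4), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPcoa:
    def test_planar_points_reconstructed(self, rng):
        pts = rng.random((10, 2))
        res = nb.pcoa(dm_from_points(pts))
        got = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(got, squareform(pdist(pts)), atol=1e-8)

    def test_collinear_points_have_one_axis(self):
        res = nb.pcoa(dm_from_points([[0.0], [1.0], [2.0]]))
        assert res.eigenvalues[0] > 1e-6
        assert abs(res.eigenvalues[1]) < 1e-9
        assert res.coordinates.shape[1] == 1

    def test_positive_fractions_sum_to_one(self, rng):
        res = nb.pcoa(dm_from_points(rng.random((8, 4))))
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.random((9, 3))
        dm = dm_from_points(pts)
        ours = nb.pcoa(dm)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
        assert np.allclose(ours.eigenvalues[:8],
                           np.sort(theirs.eigvals.to_numpy())[::-1][:8], atol=1e-8)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            nb.pcoa(dm_from_points([[0.0], [1.0]]))


class TestPermanova:
    def test_perfect_separation_r2_one(self):
        pts = [[0, 0], [0, 0], [0, 0], [5, 5], [5, 5], [5, 5]]
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAABBB")}, index=dm.index)
        res = nb.permanova(dm, meta, "g", n_perm=99, seed=0)
        assert res.at["g", "R2"] == pytest.approx(1.0)

    def test_perfect_separation_enumeration_p(self):
        # exhaustive label enumeration gives p = 2/20 = 0.1
        pts = [[0.0], [0.1], [-0.1], [5.0], [5.1], [4.9]]
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAABBB")}, index=dm.index)
        res = nb.permanova(dm, meta, "g", n_perm=999, seed=42)
        assert res.at["g", "p"] == pytest.approx(0.1, abs=0.03)

    def test_ss_decomposition_two_factor(self, rng):
        pts = rng.random((24, 5))
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": ["A", "B"] * 12,
                             "ph": ["x"] * 8 + ["y"] * 8 + ["z"] * 8},
                            index=dm.index)
        for formula in ("g", "g + ph", "g * ph"):
            res = nb.permanova(dm, meta, formula, n_perm=9, seed=1)
            terms = res.drop(index=["Total"])
            assert terms["SumsOfSqs"].sum() == pytest.approx(
                res.at["Total", "SumsOfSqs"], abs=1e-9)
        res = nb.permanova(dm, meta, "g * ph", n_perm=9, seed=1)
        assert list(res["df"].iloc[:3]) == [1, 2, 2]

    def test_one_factor_statistic_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        pts = rng.random((15, 4))
        dm = dm_from_points(pts)
        grouping = list("AAAAABBBBBCCCCC")
        meta = pd.DataFrame({"g": grouping}, index=dm.index)
        ours = nb.permanova(dm, meta, "g", n_perm=9, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index)),
            grouping=grouping, permutations=9)
        assert ours.at["g", "F"] == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_shuffled_labels_give_uniform_p(self, rng):
        rejections = 0
        for s in range(100):
            pts = rng.random((12, 3))
            dm = dm_from_points(pts)
            meta = pd.DataFrame({"g": rng.permutation(list("AAAAAABBBBBB"))},
                                index=dm.index)
            p = nb.permanova(dm, meta, "g", n_perm=99, seed=s).at["g", "p"]
            rejections += p <= 0.05
        assert rejections <= 13  # ~5% expected under the null

    def test_confounded_factor_rejected(self):
        dm = dm_from_points([[0.0], [1.0], [2.0]])
        meta = pd.DataFrame({"g": list("ABC")}, index=dm.index)
        with pytest.raises(ValueError, match="confounded"):
            nb.permanova(dm, meta, "g")

    def test_detects_planted_phylum_shift(self):
        # community-scale group effect (all Proteobacteria up e-fold in V)
        detected = 0
        for s in range(20):
            design = SyntheticDesign(phase_labels=("stimulus",), n_per_cell=18,
                                     n_water_per_cell=0, n_feed_per_diet=0)
            _, tax, _ = generate_community(design, seed=50000 + s)
            prot = tuple(tax.index[tax["phylum"] == "Proteobacteria"])
            eff = EffectSpec(prot, (("V", "stimulus"),), 1.0)
            counts, _, meta = generate_community(design, effects=(eff,),
                                                 seed=50000 + s, taxonomy=tax)
            dm = nb.bray_curtis(to_relative_abundance(counts))
            p = nb.permanova(dm, meta, "group", n_perm=199, seed=s).at["group", "p"]
            detected += p <= 0.05
        assert detected >= 18


class TestPermdisp:
    def test_coincident_groups_zero_dispersion(self):
        pts = [[1, 1]] * 3 + [[4, 4]] * 3
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAABBB")}, index=dm.index)
        res = nb.permdisp(dm, meta, "g", n_perm=99, seed=0)
        assert np.allclose(res.dispersions, 0.0)

    def test_wider_group_has_larger_dispersion(self):
        pts = [[-3.0], [3.0], [-3.0], [3.0], [-1.0], [1.0], [-1.0], [1.0]]
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAAABBBB")}, index=dm.index)
        res = nb.permdisp(dm, meta, "g", n_perm=99, seed=0)
        assert res.dispersions["A"] > res.dispersions["B"]

    def test_centroid_option_and_determinism(self, rng):
        pts = rng.random((10, 3))
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAAAABBBBB")}, index=dm.index)
        a = nb.permdisp(dm, meta, "g", n_perm=99, center="centroid", seed=3)
        b = nb.permdisp(dm, meta, "g", n_perm=99, center="centroid", seed=3)
        assert a.p == b.p and a.F == pytest.approx(b.F)

    def test_single_sample_group_rejected(self):
        dm = dm_from_points([[0.0], [1.0], [2.0], [3.0]])
        meta = pd.DataFrame({"g": list("AABC")}, index=dm.index)
        with pytest.raises(ValueError, match="<2 samples"):
            nb.permdisp(dm, meta, "g")


class TestPairwisePermanova:
    def test_two_levels_equals_single_test(self, rng):
        pts = rng.random((10, 3))
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAAAABBBBB")}, index=dm.index)
        pw = nb.pairwise_permanova(dm, meta, "g", n_perm=99, seed=0)
        single = nb.permanova(dm, meta, "g", n_perm=99, seed=0)
        assert len(pw) == 1
        assert pw["F"].iloc[0] == pytest.approx(single.at["g", "F"])
        assert pw["p_adj"].iloc[0] == pw["p"].iloc[0]  # identity adjustment

    def test_three_levels_bh_matches_oracle(self, rng):
        pts = rng.random((12, 3))
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAAABBBBCCCC")}, index=dm.index)
        pw = nb.pairwise_permanova(dm, meta, "g", n_perm=99, seed=1)
        assert len(pw) == 3
        for a in (0.05, 0.3, 0.7):
            np.testing.assert_array_equal(pw["p_adj"].to_numpy() <= a,
                                          bh_stepup_reject(pw["p"].to_numpy(), a))

    def test_single_sample_level_skipped_with_note(self, rng):
        pts = rng.random((7, 2))
        dm = dm_from_points(pts)
        meta = pd.DataFrame({"g": list("AAABBBC")}, index=dm.index)
        pw = nb.pairwise_permanova(dm, meta, "g", n_perm=49, seed=2)
        noted = pw[pw["note"] != ""]
        assert len(noted) == 2 and noted["p"].isna().all()
        assert pd.notna(pw.loc["A vs B", "p"])
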