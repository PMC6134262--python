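import itertools
import math

import numpy as np
import pytest

from psmkit import DistanceMatrix, euclidean_matrix, meandist, permanova, permdisp
from psmkit.feature_io import ValidationError


def brute_force_permanova_p(x, labels):
    """Independent oracle: classical one-way ANOVA F over every distinct
    assignment of the label multiset; p = #{F >= F_obs}/n_assignments."""
    x = np.asarray(x, float)

    def anova_f(lab):
        lab = np.asarray(lab)
        grand = x.mean()
        ss_a = sum((x[lab == g].mean() - grand) ** 2 * (lab == g).sum() for g in set(lab))
        ss_w = sum(((x[lab == g] - x[lab == g].mean()) ** 2).sum() for g in set(lab))
        a, n = len(set(lab)), len(x)
        return (ss_a / (a - 1)) / (ss_w / (n - a)) if ss_w > 0 else math.inf

    f_obs = anova_f(labels)
    arrangements = set(itertools.permutations(labels))
    count = sum(anova_f(arr) >= f_obs - 1e-12 for arr in arrangements)
    return f_obs, count / len(arrangements), len(arrangements)


class TestPermanovaIdentity:
    """1-D data x=(0,1,10,11), groups (A,A,B,B): pseudo-F on Euclidean
    distances equals the classical one-way ANOVA F (SS_A=100, SS_W=1)."""

    x = np.array([0.0, 1.0, 10.0, 11.0])
    labels = ["A", "A", "B", "B"]

    def test_pseudo_f_equals_hand_anova(self):
        D = euclidean_matrix(self.x)
        res = permanova(D, self.labels, method="exact")
        assert res.F == pytest.approx(200.0, abs=1e-10)
        assert res.r2 == pytest.approx(100.0 / 101.0, abs=1e-12)
        assert res.df_between == 1 and res.df_within == 2

    def test_exact_p_matches_brute_force_enumeration(self):
        f_oracle, p_oracle, n_arr = brute_force_permanova_p(self.x, self.labels)
        assert f_oracle == pytest.approx(200.0, abs=1e-10)
        assert n_arr == 6  # C(4,2) distinct assignments of the label multiset
        D = euclidean_matrix(self.x)
        res = permanova(D, self.labels, method="exact")
        assert res.n_perm == 6
        assert res.p == pytest.approx(p_oracle)  # = 2/6: complement ties F_obs

    def test_matches_skbio_pseudo_f(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5))
        D = euclidean_matrix(X)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = permanova(D, labels, n_perm=99, seed=0, method="monte-carlo")
        sk = sk_permanova(SkDM(D.d, ids=D.sample_ids), grouping=list(labels), permutations=0)
        assert res.F == pytest.approx(sk["test statistic"], abs=1e-10)


class TestPermanovaBehaviour:
    def test_seeded_stream_is_reproducible(self):
        rng = np.random.default_rng(1)
        D = euclidean_matrix(rng.normal(size=(16, 3)))
        labels = ["a", "b"] * 8
        r1 = permanova(D, labels, n_perm=299, seed=42, method="monte-carlo")
        r2 = permanova(D, labels, n_perm=299, seed=42, method="monte-carlo")
        assert r1.p == r2.p and r1.observed_ge_count == r2.observed_ge_count

    def test_strata_restriction_preserves_multisets(self):
        rng = np.random.default_rng(2)
        D = euclidean_matrix(rng.normal(size=(12, 2)))
        labels = np.array(["a", "a", "b", "b"] * 3)
        strata = np.repeat(["s1", "s2", "s3"], 4)
        # check_strata asserts the per-stratum label multiset on every draw
        res = permanova(D, labels, strata=strata, n_perm=199, seed=3,
                        method="monte-carlo", check_strata=True)
        assert 0 < res.p <= 1

    def test_exact_agrees_with_monte_carlo_within_binomial_error(self):
        rng = np.random.default_rng(5)
        D = euclidean_matrix(rng.normal(size=(8, 2)))
        labels = ["a"] * 4 + ["b"] * 4
        exact = permanova(D, labels, method="exact")
        mc = permanova(D, labels, n_perm=4999, seed=7, method="monte-carlo")
        se = math.sqrt(exact.p * (1 - exact.p) / 4999)
        assert abs(mc.p - exact.p) < 4 * se + 2 / 4999

    def test_p_never_zero_in_monte_carlo(self):
        x = np.array([0.0, 0.01, 0.02, 10.0, 10.01, 10.02])
        D = euclidean_matrix(x)
        res = permanova(D, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0, method="monte-carlo")
        assert res.p >= 1 / 100

    def test_single_group_rejected(self):
        D = euclidean_matrix(np.arange(4.0))
        with pytest.raises(ValidationError, match="2 groups"):
            permanova(D, ["a"] * 4)

    def test_degenerate_within_zero(self):
        x = np.array([0.0, 0.0, 5.0, 5.0])
        D = euclidean_matrix(x)
        res = permanova(D, ["a", "a", "b", "b"], method="exact")
        assert math.isinf(res.F) and res.degenerate
        assert 0 < res.p <= 1


class TestPermdisp:
    def test_equal_dispersions_f_zero(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [10.0, 0.0], [12.0, 0.0]])
        D = euclidean_matrix(pts)
        res = permdisp(D, ["A", "A", "B", "B"], center_type="centroid", n_perm=99, seed=0)
        np.testing.assert_allclose(res.distances_to_center, 1.0, atol=1e-9)
        assert res.F == 0.0

    def test_unequal_dispersions_detected(self):
        # dispersions 1 vs 5 on a line; hand ANOVA on known z
        x = np.array([0.0, 2.0, 20.0, 30.0, 40.0, 50.0])
        D = euclidean_matrix(x)
        labels = ["A", "A", "B", "B", "B", "B"]
        res = permdisp(D, labels, center_type="centroid", n_perm=999, seed=1)
        np.testing.assert_allclose(np.sort(res.distances_to_center[:2]), [1.0, 1.0], atol=1e-9)
        np.testing.assert_allclose(np.sort(res.distances_to_center[2:]), [5.0, 5.0, 15.0, 15.0],
                                   atol=1e-9)
        z = res.distances_to_center
        grand = z.mean()
        ss_b = 2 * (z[:2].mean() - grand) ** 2 + 4 * (z[2:].mean() - grand) ** 2
        ss_w = ((z[:2] - z[:2].mean()) ** 2).sum() + ((z[2:] - z[2:].mean()) ** 2).sum()
        f_hand = (ss_b / 1) / (ss_w / 4)
        assert res.F == pytest.approx(f_hand, rel=1e-9)
        assert res.F > 0

    def test_euclidean_geometry_correction_is_noop(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 3))
        D = euclidean_matrix(X)
        labels = ["a"] * 5 + ["b"] * 5
        res = permdisp(D, labels, center_type="centroid", n_perm=99, seed=0)
        for g, lab in ((slice(0, 5), "a"), (slice(5, 10), "b")):
            c = X[g].mean(axis=0)
            z_direct = np.linalg.norm(X[g] - c, axis=1)
            np.testing.assert_allclose(np.sort(res.distances_to_center[g]),
                                       np.sort(z_direct), atol=1e-8)

    def test_matches_skbio_centroid_distances(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permdisp as sk_permdisp

        # Euclidean geometry: no negative eigenvalues, so the oracle's
        # real-axes-only embedding and ours coincide
        rng = np.random.default_rng(11)
        X = rng.lognormal(size=(10, 6))
        D = euclidean_matrix(X)
        labels = ["a"] * 5 + ["b"] * 5
        res = permdisp(D, labels, center_type="centroid", n_perm=99, seed=0)
        sk = sk_permdisp(SkDM(D.d, ids=D.sample_ids), grouping=list(labels),
                         test="centroid", permutations=0)
        assert res.F == pytest.approx(sk["test statistic"], rel=1e-6)

    def test_spatial_median_default_runs(self):
        rng = np.random.default_rng(3)
        D = euclidean_matrix(rng.normal(size=(12, 4)))
        res = permdisp(D, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=0)
        assert res.center_type == "spatial_median"
        assert (res.distances_to_center >= 0).all()

    def test_groups_of_one_rejected(self):
        D = euclidean_matrix(np.arange(3.0))
        with pytest.raises(ValidationError, match="fewer than 2"):
            permdisp(D, ["a", "a", "b"])


class TestMeandist:
    def test_two_singletons(self):
        D = DistanceMatrix(["s1", "s2"], np.array([[0.0, 0.4], [0.4, 0.0]]), "euclidean")
        md = meandist(D, ["g1", "g2"])
        assert md.m[0, 1] == pytest.approx(0.4)
        assert md.singleton.all()
        assert np.isnan(md.m[0, 0]) and np.isnan(md.m[1, 1])

    def test_identical_points_split_labels(self):
        X = np.zeros((4, 2))
        D = euclidean_matrix(X)
        md = meandist(D, ["a", "a", "b", "b"])
        assert md.m[0, 0] == 0.0 and md.m[1, 1] == 0.0 and md.m[0, 1] == 0.0
        assert not md.centroid_separation.any()

    def test_centroid_shift_flags_separation(self, sim_pair):
        pos, _, real = sim_pair
        # inject a pure centroid shift by scaling one condition's intensities
        from conftest import small_table
        from psmkit import canberra_matrix
        X = pos.intensities.copy()
        warm = pos.conditions == "warm"
        X[warm, : X.shape[1] // 2] *= 4.0
        D = canberra_matrix(small_table(X, conditions=list(pos.conditions)))
        md = meandist(D, pos.conditions)
        i, j = md.groups.index("ambient"), md.groups.index("warm")
        assert md.m[i, j] > md.m[i, i] and md.m[i, j] > md.m[j, j]
        assert md.centroid_separation[i, j]
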