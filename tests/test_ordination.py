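"""Correspondence analysis identities and the ANOSIM permutation test."""

from itertools import permutations

import numpy as np
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency, rankdata
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from coralguild.ordination import (
    anosim,
    community_dissimilarity,
    correspondence_analysis,
)


def random_tables(n_tables=12, seed=4):
    rng = np.random.default_rng(seed)
    for _ in range(n_tables):
        shape = rng.integers(3, 8, size=2)
        yield rng.integers(1, 20, size=shape).astype(float)


class TestCorrespondenceAnalysis:
    def test_perfect_association_inertia_one(self):
        res = correspondence_analysis(np.array([[10.0, 0.0], [0.0, 10.0]]))
        assert res.total_inertia == pytest.approx(1.0)
        assert res.inertia_pct[0] == pytest.approx(100.0)

    def test_proportional_rows_have_zero_inertia(self):
        res = correspondence_analysis(np.array([[2.0, 4.0, 6.0], [1.0, 2.0, 3.0]]))
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_inertia_equals_pearson_chi2_over_n(self):
        for x in random_tables():
            res = correspondence_analysis(x)
            chi2 = chi2_contingency(x, correction=False).statistic
            assert res.total_inertia == pytest.approx(chi2 / x.sum(), abs=1e-9)

    def test_inertia_percentages_sum_to_100(self):
        for x in random_tables(seed=9):
            res = correspondence_analysis(x)
            assert res.inertia_pct.sum() == pytest.approx(100.0, abs=1e-9)
            assert (np.diff(res.inertia) <= 1e-12).all()  # non-increasing

    def test_row_coordinates_reproduce_chi_square_distances(self):
        for x in random_tables(seed=2):
            res = correspondence_analysis(x)
            d_ca = squareform(
                np.sqrt(
                    ((res.row_coords[:, None, :] - res.row_coords[None, :, :]) ** 2).sum(-1)
                ),
                checks=False,
            )
            d_chi = squareform(community_dissimilarity(x, metric="chi_square"), checks=False)
            assert d_ca == pytest.approx(d_chi, abs=1e-8)

    def test_agrees_with_skbio_ca(self):
        from skbio.stats.ordination import ca
        import pandas as pd

        x = next(random_tables(1, seed=33))
        ours = correspondence_analysis(x)
        ref = ca(pd.DataFrame(x), scaling=1)
        assert ours.inertia_pct / 100 == pytest.approx(
            ref.proportion_explained.values[: len(ours.inertia_pct)], abs=1e-8
        )

    def test_empty_rows_dropped_with_ids(self):
        x = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        res = correspondence_analysis(x, row_ids=["a", "b", "c"])
        assert res.row_ids == ["a", "c"]
        assert res.row_coords.shape[0] == 2

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            correspondence_analysis(np.array([[5.0, 0.0], [0.0, 0.0]]))


class TestCommunityDissimilarity:
    def test_identical_rows_distance_zero(self):
        x = np.array([[3.0, 1.0], [3.0, 1.0]])
        for metric in ("bray_curtis", "chi_square"):
            assert community_dissimilarity(x, metric)[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_bray_curtis_one(self):
        x = np.array([[5.0, 0.0], [0.0, 7.0]])
        assert community_dissimilarity(x, "bray_curtis")[0, 1] == pytest.approx(1.0)

    def test_hand_computed_values_on_3x2_table(self):
        x = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]])
        bc = community_dissimilarity(x, "bray_curtis")
        # BC(r0, r1) = 1 - 2*min_sum/(sum0+sum1) = 1 - 2*1/4
        assert bc[0, 1] == pytest.approx(0.5)
        assert bc[0, 2] == pytest.approx(1.0)
        chi = community_dissimilarity(x, "chi_square")
        # profiles (1,0), (.5,.5), (0,1); column masses (.5,.5)
        # d(0,1) = sqrt(.5^2/.5 + .5^2/.5) = 1; d(0,2) = sqrt(1/.5 + 1/.5) = 2
        assert chi[0, 1] == pytest.approx(1.0)
        assert chi[0, 2] == pytest.approx(2.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            community_dissimilarity(np.array([[1.0, 1.0], [0.0, 0.0]]))


def _exhaustive_anosim_p(d, groups):
    """Exact p over all relabelings (oracle for small n)."""
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros_like(d)
    ranks[iu] = rankdata(d[iu])
    ranks = ranks + ranks.T
    m = n * (n - 1) / 2

    def r_stat(labels):
        labels = np.asarray(labels)
        same = labels[:, None] == labels[None, :]
        w = ranks[iu][same[iu]].mean()
        b = ranks[iu][~same[iu]].mean()
        return (b - w) / (m / 2)

    obs = r_stat(groups)
    rs = [r_stat(p) for p in permutations(groups)]
    return obs, sum(r >= obs for r in rs) / len(rs)


class TestAnosim:
    d_sep = np.array(
        [[0, 1, 8, 9], [1, 0, 7, 6], [8, 7, 0, 2], [9, 6, 2, 0]], dtype=float
    )
    groups = ["a", "a", "b", "b"]

    def test_maximal_separation_gives_r_one(self):
        res = anosim(self.d_sep, self.groups, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_agrees_with_skbio(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 3))
        pts[4:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        groups = ["x"] * 4 + ["y"] * 4
        ours = anosim(d, groups, n_perm=999, seed=1)
        ref = skbio_anosim(DistanceMatrix(d), groups, permutations=999)
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_monte_carlo_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(6, 2))
        pts[3:] += 0.8
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        groups = ["a"] * 3 + ["b"] * 3
        obs, p_exact = _exhaustive_anosim_p(d, groups)
        res = anosim(d, groups, n_perm=10_000, seed=3)
        assert res.R == pytest.approx(obs)
        se = np.sqrt(p_exact * (1 - p_exact) / 10_000)
        assert abs(res.p - p_exact) < 3 * se + 1e-4

    def test_null_symmetry_mean_r_near_zero(self):
        rng = np.random.default_rng(0)
        rs = []
        for seed in range(200):
            pts = rng.normal(size=(8, 2))
            d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            rs.append(anosim(d, labels, n_perm=1, seed=seed).R)
        assert abs(np.mean(rs)) < 0.05

    def test_p_never_zero(self):
        res = anosim(self.d_sep, self.groups, n_perm=9, seed=0)
        assert res.p >= 1 / 10

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 members"):
            anosim(self.d_sep, ["a", "a", "a", "b"], n_perm=9)

    def test_asymmetric_matrix_rejected(self):
        d = self.d_sep.copy()
        d[0, 1] = 3
        with pytest.raises(ValueError, match="symmetric"):
            anosim(d, self.groups, n_perm=9)
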