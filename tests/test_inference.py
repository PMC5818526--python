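"""Group comparisons, PERMANOVA, Moran's I and the Mantel test."""

import numpy as np
import pytest

from traitpd.inference import compare_groups, mantel, morans_i, permanova


class TestCompareGroups:
    # fixed 3 x 5 design with well-behaved residuals
    VALUES = np.array(
        [5.1, 4.8, 5.3, 5.0, 4.9, 6.2, 6.0, 6.4, 6.1, 5.9, 5.2, 5.4, 5.0, 5.3, 5.1]
    )
    GROUPS = np.array(["g1"] * 5 + ["g2"] * 5 + ["g3"] * 5)

    def test_f_statistic_matches_sums_of_squares_oracle(self):
        """Explicit SSB/SSW arithmetic reproduces the ANOVA F."""
        res = compare_groups(self.VALUES, self.GROUPS)
        assert res.method == "anova+tukey"
        grand = self.VALUES.mean()
        ssb = sum(
            5 * (self.VALUES[self.GROUPS == g].mean() - grand) ** 2
            for g in ("g1", "g2", "g3")
        )
        ssw = sum(
            ((self.VALUES[self.GROUPS == g] - self.VALUES[self.GROUPS == g].mean()) ** 2).sum()
            for g in ("g1", "g2", "g3")
        )
        f_oracle = (ssb / 2) / (ssw / 12)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-8)

    def test_shifted_group_flagged_in_pairwise_letters(self):
        """Only pairs involving the group shifted by 3 pooled SDs differ."""
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, 30)
        values = base.copy()
        values[20:] += 3.0  # shift group c by 3 SDs
        groups = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        res = compare_groups(values, groups)
        sig = {
            frozenset((r.group_a, r.group_b))
            for r in res.pairwise.itertuples()
            if r.p_adj < 0.05
        }
        assert sig == {frozenset(("a", "c")), frozenset(("b", "c"))}
        # letters: a and b share one, c stands alone
        assert res.letters["a"] == res.letters["b"]
        assert set(res.letters["c"]) & set(res.letters["a"]) == set()

    def test_nonnormal_data_routes_to_kruskal_dunn(self):
        rng = np.random.default_rng(5)
        values = np.concatenate(
            [rng.lognormal(0, 2, 15), rng.lognormal(2.5, 2, 15), rng.lognormal(0, 2, 15)]
        )
        groups = np.array(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
        res = compare_groups(values, groups)
        assert res.shapiro_p < 0.05
        assert res.method == "kruskal+dunn"
        assert {"p_adj"} <= set(res.pairwise.columns)

    def test_type_one_error_near_nominal(self):
        """Null data from one normal: global p rejects at ~5%."""
        rng = np.random.default_rng(123)
        groups = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            res = compare_groups(rng.normal(size=24), groups)
            rejections += res.p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.013)

    def test_small_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


class TestPermanova:
    def test_four_point_hand_example(self):
        """All pairwise distances 1, two groups of 2: F = 1 and p = 1."""
        d = 1.0 - np.eye(4)
        res = permanova(d, np.array(["a", "a", "b", "b"]), n_perm=99, seed=0)
        # SS_total = 6/4 = 1.5; SS_within = 2 * (1/2) = 1.0; F = (0.5/1)/(1/2)
        assert res.observed == pytest.approx(1.0, abs=1e-12)
        assert res.p == 1.0
        assert res.r_squared == pytest.approx(0.5 / 1.5, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_implementation(self, seed):
        """Pseudo-F agrees with scikit-bio's PERMANOVA to 1e-8."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(seed)
        n = 12 + seed
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        sizes = [n // 3, n // 3, n - 2 * (n // 3)]
        labels = np.repeat(["a", "b", "c"], sizes)
        mine = permanova(d, labels, n_perm=9, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d), labels.tolist(), permutations=9
        )
        assert mine.observed == pytest.approx(ref["test statistic"], abs=1e-8)

    def test_strong_separation_reaches_minimum_p(self):
        """Two tight clusters far apart: p = 1/(n_perm + 1)."""
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, (12, 2)), rng.normal(50, 0.1, (12, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array(["a"] * 12 + ["b"] * 12)
        res = permanova(d, labels, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        r1 = permanova(d, labels, n_perm=499, seed=7)
        r2 = permanova(d, labels, n_perm=499, seed=7)
        assert r1.p == r2.p and r1.observed == r2.observed

    def test_invalid_matrix_raises(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            permanova(bad, np.array(["a", "b"]), n_perm=9)


class TestMoransI:
    def test_gradient_variable_is_positively_autocorrelated(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 100, (25, 2))
        values = coords[:, 0] / 100 + rng.normal(0, 0.05, 25)
        res = morans_i(values, coords, n_perm=999, seed=0)
        assert res.observed > 0
        assert res.p <= 0.01

    def test_null_mean_matches_analytic_expectation(self):
        """Permutation mean of I is -1/(n-1) under exchangeability."""
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, (25, 2))
        values = rng.normal(size=25)
        res = morans_i(values, coords, n_perm=10_000, seed=1)
        assert res.null_mean == pytest.approx(-1 / 24, abs=0.005)

    def test_constant_variable_raises(self):
        coords = np.random.default_rng(0).uniform(0, 10, (6, 2))
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(6), coords, n_perm=9)

    def test_duplicate_coordinates_raise(self):
        coords = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="duplicate"):
            morans_i(np.arange(4.0), coords, n_perm=9)


class TestMantel:
    @staticmethod
    def _dist(points):
        return np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))

    def test_self_comparison_gives_r_one_and_min_p(self):
        rng = np.random.default_rng(0)
        d = self._dist(rng.normal(size=(12, 2)))
        res = mantel(d, d, n_perm=9999, seed=0)
        assert res.observed == pytest.approx(1.0)
        assert res.p == pytest.approx(1e-4)

    def test_independent_matrices_give_near_zero_mean_r(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(30):
            a = self._dist(rng.normal(size=(10, 2)))
            b = self._dist(rng.normal(size=(10, 2)))
            rs.append(mantel(a, b, n_perm=9, seed=0).observed)
        assert abs(np.mean(rs)) < 0.1

    def test_agrees_with_independent_implementation(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(2)
        a = self._dist(rng.normal(size=(12, 2)))
        b = a + rng.normal(0, 0.3, a.shape)
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        b = np.abs(b)
        r_ref, _, _ = skbio_stats.mantel(a, b, method="pearson", permutations=9)
        res = mantel(a, b, n_perm=9, seed=0)
        assert res.observed == pytest.approx(r_ref, abs=1e-10)

    def test_constant_triangle_raises(self):
        d = 1.0 - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel(d, d, n_perm=9)


def test_permutation_p_is_never_zero():
    """The +1 rule bounds every permutation p away from zero."""
    rng = np.random.default_rng(9)
    pts = np.vstack([rng.normal(0, 0.01, (4, 2)), rng.normal(100, 0.01, (4, 2))])
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = np.array(["a"] * 4 + ["b"] * 4)
    for n_perm in (9, 99, 999):
        assert permanova(d, labels, n_perm=n_perm, seed=0).p >= 1 / (n_perm + 1)
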