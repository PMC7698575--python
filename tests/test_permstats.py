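import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway, rankdata

from fishpigment.permstats import (
    DistanceMatrix,
    anosim,
    anosim_pairwise,
    anosim_twoway,
    anova_tukey,
    distance_matrix,
    mantel,
)


def naive_distance(X, metric):
    n = len(X)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            diff = np.asarray(X[i]) - np.asarray(X[j])
            d[i, j] = np.abs(diff).sum() if metric == "manhattan" else np.sqrt((diff**2).sum())
    return d


def naive_anosim_R(d, groups):
    """Rank-table ANOSIM R with explicit loops (independent of the engine)."""
    n = len(groups)
    pairs, dists = [], []
    for i in range(n):
        for j in range(i + 1, n):
            pairs.append(groups[i] == groups[j])
            dists.append(d[i, j])
    ranks = rankdata(dists)
    within = [r for r, same in zip(ranks, pairs) if same]
    between = [r for r, same in zip(ranks, pairs) if not same]
    M = len(ranks)
    return (np.mean(between) - np.mean(within)) / (M / 2)


def clustered_dm(rng, n_per_group, k, sep):
    X = np.concatenate(
        [rng.normal(loc=g * sep, size=(n_per_group, 2)) for g in range(k)]
    )
    groups = np.repeat(np.arange(k), n_per_group)
    return distance_matrix(X, "euclidean"), groups


class TestDistanceMatrix:
    def test_manhattan_pair(self):
        dm = distance_matrix(np.array([[0, 0], [1, 1]]), "manhattan")
        assert dm.d[0, 1] == 2

    def test_euclidean_3_4_5(self):
        dm = distance_matrix(np.array([[0, 0], [3, 4]]), "euclidean")
        assert dm.d[0, 1] == 5

    @pytest.mark.parametrize("metric", ["manhattan", "euclidean"])
    def test_matches_naive_loop(self, metric):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(6, 2))
        dm = distance_matrix(X, metric)
        assert np.allclose(dm.d, naive_distance(X, metric))

    def test_missing_rows_dropped_with_warning(self, caplog):
        X = np.array([[0.0, 0], [1, np.nan], [2, 2]])
        with caplog.at_level("WARNING"):
            dm = distance_matrix(X, "manhattan", labels=["a", "b", "c"])
        assert dm.labels == ("a", "c")
        assert "dropping" in caplog.text

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix(np.array([[1.0, 2.0]]), "manhattan")

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0.0]]))


class TestAnosim:
    def test_perfect_separation_R_is_1(self):
        rng = np.random.default_rng(0)
        dm, groups = clustered_dm(rng, 5, 2, sep=100)
        res = anosim(dm, groups, n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_matches_naive_rank_table(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            X = rng.normal(size=(9, 2))
            groups = rng.permutation(np.repeat([0, 1, 2], 3))
            dm = distance_matrix(X, "manhattan")
            res = anosim(dm, groups, n_perm=9, seed=1)
            assert res.R == pytest.approx(naive_anosim_R(dm.d, groups), abs=1e-12)

    def test_matches_skbio_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(42)
        X = rng.normal(size=(12, 2))
        groups = np.repeat(["a", "b", "c"], 4)
        dm = distance_matrix(X, "euclidean")
        mine = anosim(dm, groups, n_perm=999, seed=1)
        other = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(dm.d), list(groups), permutations=999
        )
        assert mine.R == pytest.approx(float(other["test statistic"]), abs=1e-12)
        assert mine.p == pytest.approx(float(other["p-value"]), abs=0.05)

    def test_rank_based_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(9)
        dm, groups = clustered_dm(rng, 4, 3, sep=2)
        transformed = DistanceMatrix(dm.labels, np.expm1(dm.d))
        a = anosim(dm, groups, n_perm=19, seed=3)
        b = anosim(transformed, groups, n_perm=19, seed=3)
        assert a.R == pytest.approx(b.R, abs=1e-12)
        assert a.p == b.p
        assert -1 <= a.R <= 1

    def test_p_floor_and_reproducibility(self):
        rng = np.random.default_rng(0)
        dm, groups = clustered_dm(rng, 5, 2, sep=100)
        r1 = anosim(dm, groups, n_perm=99, seed=7)
        r2 = anosim(dm, groups, n_perm=99, seed=7)
        assert r1.p == r2.p and r1.R == r2.R
        assert r1.p >= 1 / 100

    def test_small_group_rejected(self):
        dm = distance_matrix(np.arange(6).reshape(-1, 1), "manhattan")
        with pytest.raises(ValueError):
            anosim(dm, [0, 0, 0, 0, 0, 1], n_perm=9)
        with pytest.raises(ValueError):
            anosim(dm, [0, 0, 0, 1, 1, 1], n_perm=0)


class TestTwoWayAnosim:
    def _crossed(self, rng, shift=0.0):
        # 2 strata x 2 groups x 4 replicates
        X, fa, fb = [], [], []
        for b in range(2):
            for a in range(2):
                X.append(rng.normal(loc=a * shift + b * 5, size=(4, 2)))
                fa += [a] * 4
                fb += [b] * 4
        return distance_matrix(np.concatenate(X), "euclidean"), np.array(fa), np.array(fb)

    def test_perfect_within_stratum_separation(self):
        rng = np.random.default_rng(1)
        dm, fa, fb = self._crossed(rng, shift=100)
        res = anosim_twoway(dm, fa, fb, n_perm=49, seed=0)
        assert res.factor_a.R == pytest.approx(1.0)

    def test_averaged_R_is_mean_of_stratum_oneways(self):
        rng = np.random.default_rng(2)
        dm, fa, fb = self._crossed(rng, shift=1.0)
        res = anosim_twoway(dm, fa, fb, n_perm=9, seed=0)
        parts = []
        for b in np.unique(fb):
            idx = np.flatnonzero(fb == b)
            parts.append(anosim(dm.submatrix(idx), fa[idx], n_perm=9, seed=0).R)
        assert res.factor_a.R == pytest.approx(np.mean(parts), abs=1e-12)
        assert res.factor_a.per_stratum_R == pytest.approx(parts, abs=1e-12)

    def test_stratum_with_one_group_rejected(self):
        rng = np.random.default_rng(3)
        dm, fa, fb = self._crossed(rng)
        fa[fb == 1] = 0  # second stratum loses all contrast in factor A
        with pytest.raises(ValueError, match="stratum"):
            anosim_twoway(dm, fa, fb, n_perm=9, seed=0)


class TestPairwiseAnosim:
    def test_identical_groups_all_adjusted_p_1(self):
        X = np.tile(np.array([[0.0, 0], [1, 1], [2, 2]]), (3, 1))
        groups = np.repeat(["a", "b", "c"], 3)
        dm = distance_matrix(X, "manhattan")
        table = anosim_pairwise(dm, groups, n_perm=99, seed=0)
        assert (table["p_bonferroni"] == 1).all()

    def test_nine_groups_give_36_pairs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(27, 2))
        groups = np.repeat([f"T{i}" for i in range(9)], 3)
        dm = distance_matrix(X, "manhattan")
        table = anosim_pairwise(dm, groups, n_perm=19, seed=0)
        assert len(table) == 36
        assert (table["p_bonferroni"] >= table["p_raw"]).all()

    def test_needs_three_groups(self):
        dm = distance_matrix(np.arange(4).reshape(-1, 1), "manhattan")
        with pytest.raises(ValueError):
            anosim_pairwise(dm, [0, 0, 1, 1], n_perm=9)


class TestMantel:
    def test_identical_matrices_r_1(self):
        rng = np.random.default_rng(5)
        dm = distance_matrix(rng.normal(size=(8, 2)), "manhattan")
        res = mantel(dm, dm, "spearman", n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_order_reversing_transform_r_minus_1(self):
        rng = np.random.default_rng(6)
        dm = distance_matrix(rng.normal(size=(7, 2)), "euclidean")
        rev = dm.d.max() + 1 - dm.d
        np.fill_diagonal(rev, 0)
        res = mantel(dm, DistanceMatrix(dm.labels, rev), "spearman", n_perm=99, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_matches_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 2))
        Y = X + rng.normal(size=X.shape)
        dma = distance_matrix(X, "manhattan")
        dmb = distance_matrix(Y, "euclidean")
        for corr in ("spearman", "pearson"):
            mine = mantel(dma, dmb, corr, n_perm=999, seed=1)
            r, p, _ = skbio_distance.mantel(
                skbio_distance.DistanceMatrix(dma.d),
                skbio_distance.DistanceMatrix(dmb.d),
                method=corr,
                permutations=999,
                alternative="greater",
            )
            assert mine.r == pytest.approx(float(r), abs=1e-12)
            assert mine.p == pytest.approx(float(p), abs=0.05)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        dma = distance_matrix(rng.normal(size=(9, 2)), "manhattan")
        dmb = distance_matrix(rng.normal(size=(9, 2)), "euclidean")
        perm = rng.permutation(9)
        dma2 = DistanceMatrix(
            tuple(dma.labels[i] for i in perm), dma.d[np.ix_(perm, perm)]
        )
        dmb2 = DistanceMatrix(
            tuple(dmb.labels[i] for i in perm), dmb.d[np.ix_(perm, perm)]
        )
        a = mantel(dma, dmb, "spearman", n_perm=199, seed=2)
        b = mantel(dma2, dmb2, "spearman", n_perm=199, seed=2)
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_label_mismatch_and_constant_matrix_rejected(self):
        rng = np.random.default_rng(9)
        dma = distance_matrix(rng.normal(size=(5, 2)), "manhattan", labels=list("abcde"))
        dmb = distance_matrix(rng.normal(size=(5, 2)), "manhattan", labels=list("abcdX"))
        with pytest.raises(ValueError, match="labels"):
            mantel(dma, dmb)
        const = DistanceMatrix(dma.labels, np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="constant"):
            mantel(dma, const, n_perm=9)


class TestAnovaTukey:
    def test_F_matches_scipy(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            vals = rng.normal(size=30)
            groups = np.repeat(["a", "b", "c"], 10)
            vals[groups == "c"] += rng.uniform(0, 2)
            mine = anova_tukey(vals, groups)
            F, p = f_oneway(*[vals[groups == g] for g in "abc"])
            assert mine.F == pytest.approx(float(F), rel=1e-10)
            assert mine.p == pytest.approx(float(p), rel=1e-8)

    def test_tukey_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multicomp")
        rng = np.random.default_rng(11)
        vals = rng.normal(size=40)
        groups = np.repeat(list("abcd"), 10)
        vals[groups == "d"] += 2
        mine = anova_tukey(vals, groups)
        other = sm.pairwise_tukeyhsd(vals, groups)
        assert np.allclose(
            mine.tukey["p_tukey"].to_numpy(), other.pvalues, atol=1e-6
        )

    def test_separated_group_gets_own_letter(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                               rng.normal(20, 1, 10)])
        groups = np.repeat(["a", "b", "c"], 10)
        res = anova_tukey(vals, groups)
        assert res.letters["a"] == res.letters["b"]
        assert set(res.letters["c"]) & set(res.letters["a"]) == set()

    def test_null_sample_usually_shares_one_letter(self):
        # a single shuffled normal sample should give one shared letter
        rng = np.random.default_rng(13)
        share = 0
        runs = 50
        for _ in range(runs):
            vals = rng.normal(size=50)
            groups = rng.permutation(np.repeat(list("abcde"), 10))
            res = anova_tukey(vals, groups)
            letters = set(res.letters.values())
            share += int(len(letters) == 1)
        assert share >= 0.9 * runs

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
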