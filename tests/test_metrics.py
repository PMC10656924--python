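"""Distance, ordination and permutation-test behaviour, checked against
closed forms, brute-force enumeration and independent library implementations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from scipy.spatial.distance import pdist, squareform

from oracles import (
    anosim_r_reference,
    exhaustive_anosim_p,
    exhaustive_permanova_p,
    pseudo_f_reference,
)

from microsucc import io as msio
from microsucc import metrics
from microsucc.errors import SchemaError


def _dm(d, ids=None, name="test"):
    d = np.asarray(d, dtype=float)
    return metrics.DistanceMatrix(
        d=d, sample_ids=ids or [f"s{i}" for i in range(d.shape[0])], metric_name=name
    ).validate()


def _rel(rows):
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])


class TestRelativeAbundance:
    def test_rows_sum_to_one(self, default_exp):
        rel = metrics.relative_abundance(default_exp.table)
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["bad", "ok"],
                              columns=["a", "b"])
        meta = pd.DataFrame(
            {"substrate": ["polyp"] * 2, "inoculum": ["bL"] * 2,
             "timepoint": [2, 2], "replicate": [1, 2]},
            index=["bad", "ok"],
        )
        with pytest.raises(SchemaError, match="bad"):
            metrics.relative_abundance(msio.CommunityTable(counts=counts, meta=meta))


class TestChao1:
    @pytest.mark.parametrize(
        "row, expected",
        [((5, 5, 5), 3.0), ((1, 1, 2), 3.5), ((1, 0, 0), 1.0)],
    )
    def test_closed_form(self, row, expected):
        assert metrics.chao1(row) == pytest.approx(expected)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            metrics.chao1((1.5, 2.0))

    def test_matches_scikit_bio(self, rng):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        for _ in range(20):
            row = rng.integers(0, 6, size=30)
            if row.sum() == 0:
                continue
            assert metrics.chao1(row) == pytest.approx(skbio_chao1(row))


class TestDistances:
    def test_identical_rows_are_zero_under_all_metrics(self):
        rel = _rel([[0.2, 0.3, 0.5]] * 3)
        for m in metrics.METRICS:
            assert np.allclose(metrics.distance_matrix(rel, m).d, 0.0)

    def test_disjoint_supports_are_one(self):
        rel = _rel([[1.0, 0.0], [0.0, 1.0]])
        for m in ("bray_curtis", "jaccard", "binary_jaccard"):
            assert metrics.distance_matrix(rel, m).d[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_closed_form(self):
        rel = _rel([[1.0, 0.0], [0.5, 0.5]])
        assert metrics.distance_matrix(rel, "bray_curtis").d[0, 1] == pytest.approx(0.5)
        # Jaccard derived from Bray-Curtis: 2d/(1+d)
        assert metrics.distance_matrix(rel, "jaccard").d[0, 1] == pytest.approx(
            2 * 0.5 / 1.5
        )

    def test_jensen_shannon_is_sqrt_of_base2_divergence(self):
        rel = _rel([[1.0, 0.0], [0.5, 0.5]])
        d = metrics.distance_matrix(rel, "jensen_shannon").d[0, 1]
        x, y = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        m = (x + y) / 2

        def kl(p, q):
            mask = p > 0
            return float((p[mask] * np.log2(p[mask] / q[mask])).sum())

        assert d == pytest.approx(np.sqrt(0.5 * kl(x, m) + 0.5 * kl(y, m)))

    def test_invariants_on_random_tables(self, rng):
        raw = rng.random((8, 5))
        rel = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True))
        for m in metrics.METRICS:
            dm = metrics.distance_matrix(rel, m).validate()
            assert dm.d.max() <= 1.0 + 1e-12

    def test_nan_rejected(self):
        rel = _rel([[np.nan, 1.0], [0.5, 0.5]])
        with pytest.raises(ValueError, match="NaN"):
            metrics.distance_matrix(rel, "bray_curtis")


class TestPcoa:
    def test_three_collinear_points(self):
        dm = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = metrics.pcoa(dm)
        coords = np.sort(res.coordinates.iloc[:, 0].to_numpy())
        assert np.allclose(coords, [-1, 0, 1], atol=1e-9)

    def test_all_zero_distances(self):
        res = metrics.pcoa(_dm(np.zeros((3, 3))))
        assert res.coordinates.shape[1] == 0

    def test_euclidean_cloud_recovered_exactly(self, rng):
        X = rng.normal(size=(15, 4))
        dm = _dm(squareform(pdist(X)))
        res = metrics.pcoa(dm)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rec - dm.d).max() < 1e-8

    def test_truncation_warning(self):
        dm = _dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        with pytest.warns(UserWarning, match="truncating"):
            res = metrics.pcoa(dm, n_axes=3)
        assert res.coordinates.shape[1] == 1

    def test_proportions_match_scikit_bio(self, rng):
        import skbio

        X = rng.normal(size=(10, 3))
        d = squareform(pdist(X))
        mine = metrics.pcoa(_dm(d))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        k = mine.proportion_explained.size
        assert np.allclose(
            mine.proportion_explained,
            ref.proportion_explained.to_numpy()[:k],
            atol=1e-8,
        )


def _two_cloud_dm(rng, n_per=3, sep=0.0):
    X = np.vstack([
        rng.normal(0, 1, size=(n_per, 3)),
        rng.normal(sep, 1, size=(n_per, 3)),
    ])
    return _dm(squareform(pdist(X))), np.array(["a"] * n_per + ["b"] * n_per)


class TestPermanova:
    def test_exhaustive_p_matches_brute_force(self, rng):
        for _ in range(3):
            dm, groups = _two_cloud_dm(rng, n_per=3, sep=1.5)
            res = metrics.permanova(dm, groups, n_permutations="exhaustive")
            assert res.p_value == pytest.approx(exhaustive_permanova_p(dm.d, groups))
            assert res.statistic == pytest.approx(pseudo_f_reference(dm.d, groups))

    def test_statistic_matches_scikit_bio(self, rng):
        import skbio

        dm, groups = _two_cloud_dm(rng, n_per=5, sep=1.0)
        mine = metrics.permanova(dm, groups, n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d), groups, permutations=0
        )
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_identical_group_clouds_give_f_near_zero(self):
        base = np.array([[0.0, 0], [1, 0], [0, 1]])
        X = np.vstack([base, base])  # group b duplicates group a exactly
        dm = _dm(squareform(pdist(X)))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = metrics.permanova(dm, groups, n_permutations="exhaustive")
        assert res.statistic < 1e-10
        assert res.p_value > 0.9

    def test_reordering_invariance_under_exhaustive_enumeration(self, rng):
        dm, groups = _two_cloud_dm(rng, n_per=3, sep=1.0)
        perm = rng.permutation(dm.n)
        dm2 = _dm(dm.d[np.ix_(perm, perm)])
        r1 = metrics.permanova(dm, groups, n_permutations="exhaustive")
        r2 = metrics.permanova(dm2, groups[perm], n_permutations="exhaustive")
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_group_rejected(self):
        dm = _dm(squareform(pdist(np.eye(3))))
        with pytest.raises(ValueError, match="fewer than 2"):
            metrics.permanova(dm, ["a", "a", "b"])


class TestPairwisePermanova:
    def test_three_groups_give_three_pairs_and_valid_bh(self, rng):
        X = np.vstack([rng.normal(i, 1, size=(4, 3)) for i in range(3)])
        dm = _dm(squareform(pdist(X)))
        groups = np.repeat(["a", "b", "c"], 4)
        out = metrics.pairwise_permanova(dm, groups, n_permutations=99, seed=1)
        assert len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        mine = metrics.benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.abs(mine - ref).max() < 1e-10


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # all between-group distances exceed all within-group distances
        d = np.array([
            [0, 1, 1, 9, 9, 9],
            [1, 0, 1, 9, 9, 9],
            [1, 1, 0, 9, 9, 9],
            [9, 9, 9, 0, 1, 1],
            [9, 9, 9, 1, 0, 1],
            [9, 9, 9, 1, 1, 0],
        ], dtype=float)
        res = metrics.anosim(_dm(d), ["a"] * 3 + ["b"] * 3,
                             n_permutations="exhaustive")
        assert res.statistic == pytest.approx(1.0)

    def test_matches_hand_ranked_reference_and_exhaustive_p(self, rng):
        dm, groups = _two_cloud_dm(rng, n_per=3, sep=1.0)
        res = metrics.anosim(dm, groups, n_permutations="exhaustive")
        assert res.statistic == pytest.approx(anosim_r_reference(dm.d, groups))
        assert res.p_value == pytest.approx(exhaustive_anosim_p(dm.d, groups))

    def test_r_matches_scikit_bio(self, rng):
        import skbio

        dm, groups = _two_cloud_dm(rng, n_per=5, sep=0.8)
        mine = metrics.anosim(dm, groups, n_permutations=99, seed=0)
        ref = skbio.stats.distance.anosim(
            skbio.DistanceMatrix(dm.d), groups, permutations=0
        )
        assert mine.statistic == pytest.approx(ref["test statistic"])

    def test_tied_distances_use_midranks(self):
        d = np.array([
            [0, 1, 2, 2],
            [1, 0, 2, 2],
            [2, 2, 0, 1],
            [2, 2, 1, 0],
        ], dtype=float)
        groups = ["a", "a", "b", "b"]
        res = metrics.anosim(_dm(d), groups, n_permutations="exhaustive")
        assert res.statistic == pytest.approx(anosim_r_reference(d, groups))


class TestKruskalWallis:
    def test_tie_free_closed_form(self):
        res = metrics.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(12 / (6 * 7) * (6**2 / 3 + 15**2 / 3) - 21)

    def test_identical_groups_give_zero(self):
        res = metrics.kruskal_wallis([2, 2], [2, 2, 2])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_on_random_instances(self, rng):
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = [rng.integers(0, 6, size=rng.integers(2, 8)).astype(float)
                      for _ in range(k)]
            if all((g == groups[0][0]).all() for g in groups):
                continue
            mine = metrics.kruskal_wallis(*groups)
            ref_h, ref_p = scipy.stats.kruskal(*groups)
            assert abs(mine.statistic - ref_h) < 1e-10
            assert abs(mine.p_value - ref_p) < 1e-10
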