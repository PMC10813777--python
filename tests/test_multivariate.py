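"""Distance-based statistics against hand computations and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from neutralstab import multivariate as mv
from neutralstab.datamodel import CountTable, ValidationError


def _euclid_dm(points, ids=None):
    d = squareform(pdist(points))
    ids = ids or [f"s{i}" for i in range(points.shape[0])]
    return mv.DistanceMatrix(d, ids)


@pytest.fixture(scope="module")
def random_counts():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(rng.poisson(15, size=(40, 14)) + 1,
                      index=[f"z{i}" for i in range(40)],
                      columns=[f"s{i}" for i in range(14)])
    return CountTable(df)


class TestAlphaDiversity:
    def test_uniform_sample_maximum_entropy(self):
        table = CountTable(pd.DataFrame({"s": [10] * 8},
                                        index=[f"z{i}" for i in range(8)]))
        alpha = mv.alpha_diversity(table)
        assert alpha.loc["s", "shannon"] == pytest.approx(np.log(8))
        assert alpha.loc["s", "pielou"] == pytest.approx(1.0)

    def test_single_taxon_degenerate(self):
        table = CountTable(pd.DataFrame({"s": [50, 0]}, index=["a", "b"]))
        alpha = mv.alpha_diversity(table)
        assert alpha.loc["s", "shannon"] == 0.0
        assert alpha.loc["s", "simpson"] == 0.0
        assert alpha.loc["s", "observed"] == 1.0

    def test_chao1_formula(self):
        # S_obs=20, F1=4, F2=2 -> chao1 = 20 + 16/4 = 24
        counts = [1] * 4 + [2] * 2 + [5] * 14
        table = CountTable(pd.DataFrame(
            {"s": counts}, index=[f"z{i}" for i in range(20)]))
        alpha = mv.alpha_diversity(table)
        assert alpha.loc["s", "chao1"] == pytest.approx(24.0)

    def test_unknown_metric_rejected(self, random_counts):
        with pytest.raises(ValidationError):
            mv.alpha_diversity(random_counts, metrics=("observed", "phylo"))


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        df = pd.DataFrame({"a": [3, 0], "b": [3, 0], "c": [0, 5]},
                          index=["x", "y"])
        dm = mv.bray_curtis(df, scale="counts")
        ids = dm.sample_ids
        assert dm.data[ids.index("a"), ids.index("b")] == 0.0
        assert dm.data[ids.index("a"), ids.index("c")] == 1.0

    def test_hand_case(self):
        df = pd.DataFrame({"u": [6, 0, 2], "v": [2, 2, 0]})
        dm = mv.bray_curtis(df, scale="counts")
        assert dm.data[0, 1] == pytest.approx(8 / 12)

    def test_matches_scipy_on_relative(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        rel = random_counts.counts / random_counts.counts.sum(axis=0)
        oracle = squareform(pdist(rel.T, "braycurtis"))
        assert np.abs(dm.data - oracle).max() < 1e-12

    def test_equal_depth_counts_equal_relative(self):
        rng = np.random.default_rng(1)
        base = rng.multinomial(500, np.full(10, 0.1), size=6).T
        df = pd.DataFrame(base)
        a = mv.bray_curtis(df, scale="counts").data
        b = mv.bray_curtis(df, scale="relative").data
        assert np.abs(a - b).max() < 1e-12


class TestPcoa:
    def test_two_samples_forced_geometry(self):
        dm = mv.DistanceMatrix(np.array([[0.0, 0.8], [0.8, 0.0]]), ["a", "b"])
        res = mv.pcoa(dm)
        coords = res.coordinates.to_numpy().ravel()
        assert np.allclose(np.sort(np.abs(coords)), [0.4, 0.4])

    def test_recovers_euclidean_cloud(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(20, 2))
        res = mv.pcoa(_euclid_dm(pts))
        coords = res.coordinates.to_numpy()[:, :2]
        centered = pts - pts.mean(axis=0)
        rot, _ = orthogonal_procrustes(coords, centered)
        assert np.abs(coords @ rot - centered).max() < 1e-8

    def test_trace_identity(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        res = mv.pcoa(dm)
        g = -0.5 * dm.data ** 2
        g = g - g.mean(0, keepdims=True) - g.mean(1, keepdims=True) + g.mean()
        total = res.eigenvalues.sum() + res.negative_eigenvalues.sum()
        assert total == pytest.approx(np.trace(g), abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_matches_skbio(self, random_counts):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa as sk_pcoa

        dm = mv.bray_curtis(random_counts)
        ours = mv.pcoa(dm)
        sk = sk_pcoa(skbio.DistanceMatrix(dm.data, ids=dm.sample_ids))
        k = len(ours.eigenvalues)
        assert np.allclose(ours.eigenvalues, sk.eigvals.values[:k], atol=1e-10)


class TestPermanova:
    def test_r2_partition_and_df(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        meta = pd.DataFrame(
            {"g": ["a"] * 7 + ["b"] * 7,
             "t": [0, 1] * 7},
            index=dm.sample_ids)
        res = mv.permanova(dm, meta, ["g", "t", "g:t"], n_perm=99, seed=0)
        tab = res.table
        r2_sum = tab.drop(index="Total")["R2"].sum()
        assert r2_sum == pytest.approx(1.0, abs=1e-9)
        assert tab.drop(index="Total")["df"].sum() == dm.n - 1

    def test_matches_skbio_single_factor(self, random_counts):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        dm = mv.bray_curtis(random_counts)
        labels = np.array(["a"] * 7 + ["b"] * 7)
        meta = pd.DataFrame({"g": labels}, index=dm.sample_ids)
        ours = mv.permanova(dm, meta, ["g"], n_perm=99, seed=0)
        sk = sk_permanova(skbio.DistanceMatrix(dm.data, ids=dm.sample_ids),
                          labels, permutations=99)
        assert ours.table.loc["g", "F"] == pytest.approx(
            sk["test statistic"], abs=1e-10)

    def test_exact_enumeration_two_groups(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 0.8
        dm = _euclid_dm(pts)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        meta = pd.DataFrame({"g": labels}, index=dm.sample_ids)

        # independent oracle: classic one-factor decomposition from squared
        # distances, enumerated over all 20 distinct 3+3 assignments
        d2 = dm.data ** 2

        def pseudo_f(lab):
            n = 6
            ss_t = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = 0.0
            for g in ("a", "b"):
                idx = np.flatnonzero(lab == g)
                ss_w += d2[np.ix_(idx, idx)][np.triu_indices(3, 1)].sum() / 3
            ss_a = ss_t - ss_w
            return (ss_a / 1) / (ss_w / 4)

        f_obs = pseudo_f(labels)
        splits = list(itertools.combinations(range(6), 3))
        f_all = []
        perms = []
        for split in splits:
            lab = np.array(["b"] * 6, dtype=object)
            lab[list(split)] = "a"
            f_all.append(pseudo_f(lab))
            order = list(split) + [i for i in range(6) if i not in split]
            perms.append(np.array(order))
        p_exact = np.mean([f >= f_obs - 1e-12 for f in f_all])

        # drop the identity permutation so (1+b)/(1+19) equals m/20
        perms = [o for o in perms if not (o == np.arange(6)).all()]
        res = mv.permanova(dm, meta, ["g"], permutations=perms)
        assert res.table.loc["g", "F"] == pytest.approx(f_obs, abs=1e-10)
        assert res.table.loc["g", "p"] == pytest.approx(p_exact, abs=1e-12)

    def test_aliased_term_rejected(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        meta = pd.DataFrame({"g": ["a"] * 7 + ["b"] * 7,
                             "g2": ["x"] * 7 + ["y"] * 7},
                            index=dm.sample_ids)
        with pytest.raises(ValidationError, match="g2"):
            mv.permanova(dm, meta, ["g", "g2"], n_perm=9, seed=0)

    def test_label_order_invariance(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        meta = pd.DataFrame({"g": ["a", "b"] * 7}, index=dm.sample_ids)
        res1 = mv.permanova(dm, meta, ["g"], n_perm=49, seed=3)
        order = np.random.default_rng(0).permutation(dm.n)
        dm2 = dm.permuted(order)
        res2 = mv.permanova(dm2, meta, ["g"], n_perm=49, seed=3)
        assert res1.table.loc["g", "F"] == pytest.approx(
            res2.table.loc["g", "F"], abs=1e-10)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        pts = np.vstack([np.zeros((4, 2)) + np.random.default_rng(0).normal(
            0, 0.01, size=(4, 2)), np.ones((4, 2)) * 10
            + np.random.default_rng(1).normal(0, 0.01, size=(4, 2))])
        dm = _euclid_dm(pts)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=dm.sample_ids)
        res = mv.anosim(dm, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        # permutations recreating the same split tie at R=1, so p is small
        # but not necessarily the minimum attainable
        assert res.p_value < 0.05

    def test_hand_rank_arithmetic(self):
        # 4 samples, groups {0,1} vs {2,3}; distances chosen so the rank sets
        # interleave: within = {1, 4}, between = {2, 3, 5, 6}
        d = np.zeros((4, 4))
        vals = {(0, 1): 1.0, (2, 3): 3.0, (0, 2): 2.0, (0, 3): 2.5,
                (1, 2): 4.0, (1, 3): 5.0}
        for (i, j), v in vals.items():
            d[i, j] = d[j, i] = v
        dm = mv.DistanceMatrix(d, list("abcd"))
        labels = pd.Series(["g1", "g1", "g2", "g2"], index=list("abcd"))
        res = mv.anosim(dm, labels, n_perm=9, seed=0)
        ranks = stats.rankdata([1.0, 2.0, 2.5, 4.0, 5.0, 3.0])
        r_within = (ranks[0] + ranks[5]) / 2
        r_between = (ranks[1] + ranks[2] + ranks[3] + ranks[4]) / 4
        expected = (r_between - r_within) / (6 / 2)
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_matches_skbio(self, random_counts):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        dm = mv.bray_curtis(random_counts)
        labels = np.array(["a", "b"] * 7)
        ours = mv.anosim(dm, labels, n_perm=99, seed=1)
        sk = sk_anosim(skbio.DistanceMatrix(dm.data, ids=dm.sample_ids),
                       labels, permutations=99)
        assert ours.statistic == pytest.approx(sk["test statistic"], abs=1e-12)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(7)
        stats_null = []
        for _ in range(200):
            pts = rng.normal(size=(10, 3))
            dm = _euclid_dm(pts)
            labels = np.array(["a"] * 5 + ["b"] * 5)
            rng.shuffle(labels)
            stats_null.append(mv.anosim(dm, labels, n_perm=9, seed=1).statistic)
        assert abs(np.mean(stats_null)) < 0.05

    def test_single_group_rejected(self):
        dm = _euclid_dm(np.random.default_rng(0).normal(size=(4, 2)))
        with pytest.raises(ValidationError):
            mv.anosim(dm, np.array(["a"] * 4), n_perm=9, seed=0)


class TestMrpp:
    def test_equidistant_data_a_exactly_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        dm = mv.DistanceMatrix(d, [f"s{i}" for i in range(6)])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = mv.mrpp(dm, labels, n_perm=49, seed=0)
        assert res.extras["A"] == 0.0

    def test_two_tight_clusters(self):
        rng = np.random.default_rng(2)
        pts = np.vstack([rng.normal(0, 0.01, (5, 2)),
                         rng.normal(20, 0.01, (5, 2))])
        dm = _euclid_dm(pts)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        res = mv.mrpp(dm, labels, n_perm=99, seed=0)
        assert res.extras["A"] > 0
        assert res.p_value <= 0.05

    def test_observed_delta_brute_force(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 2))
        dm = _euclid_dm(pts)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = mv.mrpp(dm, labels, n_perm=9, seed=0)
        within_a = dm.data[np.ix_([0, 1, 2], [0, 1, 2])][
            np.triu_indices(3, 1)].mean()
        within_b = dm.data[np.ix_([3, 4, 5], [3, 4, 5])][
            np.triu_indices(3, 1)].mean()
        assert res.statistic == pytest.approx(
            0.5 * within_a + 0.5 * within_b, abs=1e-12)


class TestMantel:
    def test_self_correlation_is_one(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        res = mv.mantel(dm, dm, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_transform_spearman_one(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        dm2 = mv.DistanceMatrix(dm.data ** 2, dm.sample_ids)
        res = mv.mantel(dm, dm2, n_perm=9, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_matches_skbio(self, random_counts):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        dm = mv.bray_curtis(random_counts)
        rng = np.random.default_rng(9)
        other = _euclid_dm(rng.normal(size=(dm.n, 3)), ids=dm.sample_ids)
        ours = mv.mantel(dm, other, n_perm=99, seed=0)
        r_sk, _, _ = sk_mantel(
            skbio.DistanceMatrix(dm.data, ids=dm.sample_ids),
            skbio.DistanceMatrix(other.data, ids=other.sample_ids),
            method="spearman", permutations=0, alternative="greater")
        assert ours.statistic == pytest.approx(r_sk, abs=1e-12)

    def test_id_mismatch_rejected(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        other = mv.DistanceMatrix(dm.data.copy(),
                                  [f"x{i}" for i in range(dm.n)])
        with pytest.raises(ValidationError):
            mv.mantel(dm, other)


class TestRda:
    def test_orthogonal_constraints_explain_nothing(self):
        rng = np.random.default_rng(0)
        y = pd.DataFrame(rng.normal(size=(20, 4)))
        yc = y - y.mean()
        # build a covariate orthogonal to every response column
        q, _ = np.linalg.qr(np.hstack([yc.to_numpy(),
                                       rng.normal(size=(20, 1))]))
        c = pd.DataFrame({"c": q[:, 4]}, index=y.index)
        ord_res, _ = mv.rda(y, c, n_perm=9, seed=0)
        assert ord_res.constrained_eigenvalues.sum() < 1e-20

    def test_pc1_covariate_reproduces_component(self):
        rng = np.random.default_rng(1)
        y = pd.DataFrame(rng.normal(size=(25, 5)) @ np.diag([3, 2, 1, 1, 1]))
        yc = y - y.mean()
        u, s, vt = np.linalg.svd(yc.to_numpy(), full_matrices=False)
        pc1 = yc.to_numpy() @ vt[0]
        c = pd.DataFrame({"pc1": pc1}, index=y.index)
        ord_res, _ = mv.rda(y, c, n_perm=9, seed=0)
        lam1_pca = s[0] ** 2 / (25 - 1)
        assert ord_res.constrained_eigenvalues[0] == pytest.approx(
            lam1_pca, rel=1e-9)

    def test_variance_partition(self):
        rng = np.random.default_rng(2)
        y = pd.DataFrame(rng.normal(size=(18, 6)))
        c = pd.DataFrame(rng.normal(size=(18, 2)), columns=["a", "b"],
                         index=y.index)
        ord_res, _ = mv.rda(y, c, n_perm=9, seed=0)
        total = ord_res.constrained_eigenvalues.sum() + \
            ord_res.unconstrained_eigenvalues.sum()
        expected = ((y - y.mean()) ** 2).to_numpy().sum() / (18 - 1)
        assert total == pytest.approx(expected, rel=1e-10)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(3)
        y = pd.DataFrame(rng.normal(size=(12, 3)))
        x = rng.normal(size=12)
        c = pd.DataFrame({"a": x, "b": 2 * x}, index=y.index)
        with pytest.raises(ValidationError, match="collinear"):
            mv.rda(y, c, n_perm=9, seed=0)


class TestDbrda:
    def test_euclidean_equivalence_with_rda(self):
        rng = np.random.default_rng(4)
        y = pd.DataFrame(rng.normal(size=(16, 5)),
                         index=[f"s{i}" for i in range(16)])
        c = pd.DataFrame(rng.normal(size=(16, 2)), columns=["a", "b"],
                         index=y.index)
        dm = _euclid_dm(y.to_numpy(), ids=list(y.index))
        ord_db, _ = mv.dbrda(dm, c, n_perm=9, seed=0)
        ord_rda, _ = mv.rda(y, c, n_perm=9, seed=0)
        k = min(len(ord_db.constrained_eigenvalues),
                len(ord_rda.constrained_eigenvalues))
        assert np.allclose(ord_db.constrained_eigenvalues[:k],
                           ord_rda.constrained_eigenvalues[:k], atol=1e-8)

    def test_constrained_proportion_bounds(self, random_counts):
        dm = mv.bray_curtis(random_counts)
        rng = np.random.default_rng(5)
        c = pd.DataFrame({"x": rng.normal(size=dm.n)}, index=dm.sample_ids)
        ord_res, _ = mv.dbrda(dm, c, n_perm=9, seed=0)
        assert 0.0 <= ord_res.constrained_proportion <= 1.0


class TestAnovaTukey:
    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = mv.anova_tukey(np.concatenate([a, b]),
                             np.array(["a"] * 8 + ["b"] * 8))
        t, _ = stats.ttest_ind(a, b)
        assert res.f_statistic == pytest.approx(t ** 2, rel=1e-10)

    def test_textbook_three_groups(self):
        # MSB/MSW computed by hand: groups (1,2,3), (2,3,4), (5,6,7)
        values = np.array([1, 2, 3, 2, 3, 4, 5, 6, 7], dtype=float)
        groups = np.repeat(["g1", "g2", "g3"], 3)
        grand = values.mean()
        msb = 3 * sum((values[groups == g].mean() - grand) ** 2
                      for g in ("g1", "g2", "g3")) / 2
        msw = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                  for g in ("g1", "g2", "g3")) / 6
        res = mv.anova_tukey(values, groups)
        assert res.f_statistic == pytest.approx(msb / msw, rel=1e-12)

    def test_identical_groups_one_letter(self):
        values = np.array([1.0, 2.0, 3.0] * 3)
        groups = np.repeat(["a", "b", "c"], 3)
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        res = mv.anova_tukey(values, groups)
        assert len(set(res.letters.values())) == 1


class TestHclust:
    def test_forced_topology(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        dm = mv.DistanceMatrix(d, ["A", "B", "C"])
        nwk = mv.hclust_average(dm)
        assert nwk.startswith("((A:") and "C:" in nwk

    def test_ultrametric_cophenetic_roundtrip(self):
        skbio = pytest.importorskip("skbio")
        # ultrametric distances: ((a,b):1,(c,d):2) with heights 1, 2, 4
        ids = ["a", "b", "c", "d"]
        d = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0]], dtype=float)
        dm = mv.DistanceMatrix(d, ids)
        tree = skbio.TreeNode.read([mv.hclust_average(dm)])
        for i, j in itertools.combinations(range(4), 2):
            coph = tree.find(ids[i]).distance(tree.find(ids[j]))
            assert coph == pytest.approx(d[i, j], abs=1e-9)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 3))
        ids = [f"s{i}" for i in range(7)]
        dm = _euclid_dm(pts, ids)
        order = rng.permutation(7)
        dm2 = dm.permuted(order)
        assert mv.hclust_average(dm) == mv.hclust_average(dm2)


class TestNullCalibration:
    """Type-I error of each permutation statistic under a true null."""

    @staticmethod
    def _null_dms(n_data, n, rng):
        for _ in range(n_data):
            yield _euclid_dm(rng.normal(size=(n, 3)))

    def test_anosim_mrpp_mantel_calibration(self):
        rng = np.random.default_rng(123)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        rej = {"anosim": 0, "mrpp": 0, "mantel": 0}
        n_data = 400
        for i, dm in enumerate(self._null_dms(n_data, 10, rng)):
            other = _euclid_dm(rng.normal(size=(10, 3)), ids=dm.sample_ids)
            if mv.anosim(dm, labels, n_perm=99, seed=i).p_value <= 0.05:
                rej["anosim"] += 1
            if mv.mrpp(dm, labels, n_perm=99, seed=i).p_value <= 0.05:
                rej["mrpp"] += 1
            if mv.mantel(dm, other, n_perm=99, seed=i).p_value <= 0.05:
                rej["mantel"] += 1
        for name, count in rej.items():
            rate = count / n_data
            # binomial(400, 0.05) 3-sigma band around nominal level
            assert 0.02 <= rate <= 0.085, f"{name} type-I rate {rate}"
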