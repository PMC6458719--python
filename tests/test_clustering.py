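"""Mixture clustering, family rules, hierarchical labels, term enrichment."""

import io as std_io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from floraleaf import clustering
from floraleaf.clustering import (
    ClusterModel, assign_families, fit_gmm, hclust_profiles,
    linkage_to_newick, profile_transform, select_k, term_enrichment,
)


def _blob_profiles(n_per, centers, sd, seed, d=4):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for ci, c in enumerate(centers):
        rows.append(rng.normal(c, sd, size=(n_per, d)))
        labels.extend([ci] * n_per)
    y = np.vstack(rows)
    df = pd.DataFrame(y, index=[f"f{i}" for i in range(len(y))])
    return df, np.array(labels)


class TestProfileTransform:
    def test_endpoints_of_arcsin_root(self):
        counts = pd.DataFrame({"s1": [9, 0], "s2": [0, 4]}, index=["a", "b"])
        y = profile_transform(counts)
        assert y.loc["a", "s1"] == pytest.approx(np.pi / 2)
        assert y.loc["a", "s2"] == pytest.approx(0.0)

    def test_equal_counts_give_equal_transform(self):
        counts = pd.DataFrame(np.full((1, 12), 7.0),
                              columns=[f"s{i}" for i in range(12)], index=["f"])
        y = profile_transform(counts)
        assert np.allclose(y, np.arcsin(np.sqrt(1 / 12)))

    def test_round_trip_recovers_proportions(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(50, size=(20, 6)) + 1.0,
                              columns=[f"s{i}" for i in range(6)])
        y = profile_transform(counts).to_numpy()
        p = np.sin(y) ** 2
        expected = counts.to_numpy() / counts.to_numpy().sum(axis=1, keepdims=True)
        assert np.allclose(p, expected, atol=1e-12)

    def test_zero_total_feature_rejected(self):
        counts = pd.DataFrame({"s1": [0], "s2": [0]}, index=["dead"])
        with pytest.raises(ValueError):
            profile_transform(counts)


class TestGmm:
    def test_k1_recovers_grand_mean(self):
        df, _ = _blob_profiles(50, [[0.3] * 4], 0.05, seed=2)
        model = fit_gmm(df, 1, n_restarts=2, seed=0)
        assert np.allclose(model.means[0], df.mean(axis=0), atol=1e-8)
        assert model.responsibilities.shape == (50, 1)
        assert np.allclose(model.responsibilities, 1.0)

    def test_loglik_monotone_within_em(self):
        df, _ = _blob_profiles(60, [[0.1] * 4, [0.5] * 4], 0.05, seed=3)
        model = fit_gmm(df, 2, n_restarts=3, seed=1)
        trace = np.array(model.ll_trace)
        assert (np.diff(trace) >= -1e-7).all()

    def test_separated_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        centers = [[0.1, 0.1, 0.1, 0.1], [0.5, 0.1, 0.1, 0.5],
                   [0.1, 0.5, 0.5, 0.1]]
        df, labels = _blob_profiles(100, centers, 0.04, seed=4)  # 10 sigma
        model = fit_gmm(df, 3, n_restarts=5, seed=2)
        assert adjusted_rand_score(labels, model.labels) >= 0.95

    def test_matches_sklearn_likelihood(self):
        from sklearn.mixture import GaussianMixture

        df, _ = _blob_profiles(80, [[0.1] * 4, [0.6] * 4], 0.05, seed=5)
        ours = fit_gmm(df, 2, n_restarts=5, seed=3)
        sk = GaussianMixture(2, covariance_type="diag", n_init=5,
                             random_state=0, tol=1e-8, max_iter=500,
                             reg_covar=1e-8).fit(df.to_numpy())
        theirs = sk.score(df.to_numpy()) * len(df)
        assert ours.log_likelihood == pytest.approx(theirs, rel=1e-3)

    def test_rejects_k_larger_than_n(self):
        df, _ = _blob_profiles(3, [[0.2] * 4], 0.01, seed=6)
        with pytest.raises(ValueError):
            fit_gmm(df, 5)


class TestSelectK:
    def test_icl_table_covers_range(self):
        df, _ = _blob_profiles(40, [[0.1] * 4, [0.5] * 4], 0.05, seed=7)
        model, table = select_k(df, range(1, 5), n_restarts=2, seed=0)
        assert len(table) == 4
        assert set(table["k"]) == {1, 2, 3, 4}
        assert model.icl() == pytest.approx(table["icl"].max())

    def test_single_k_range_returns_that_model(self):
        df, _ = _blob_profiles(30, [[0.2] * 4], 0.05, seed=8)
        model, table = select_k(df, [3], n_restarts=2, seed=0)
        assert model.k == 3 and len(table) == 1

    def test_feature_order_invariance(self):
        df, _ = _blob_profiles(60, [[0.1] * 4, [0.5] * 4], 0.05, seed=9)
        m1, t1 = select_k(df, range(1, 4), n_restarts=3, seed=5)
        perm = np.random.default_rng(0).permutation(len(df))
        m2, t2 = select_k(df.iloc[perm], range(1, 4), n_restarts=3, seed=5)
        assert m1.k == m2.k
        assert np.allclose(t1["icl"], t2["icl"], rtol=1e-6)


class TestFamilies:
    def _model_with_means(self, means):
        means = np.asarray(means, dtype=float)
        k, d = means.shape
        return ClusterModel(
            k, np.full(k, 1 / k), means, np.full((k, d), 1e-3),
            np.full((1, k), 1 / k), 0.0)

    def _tp(self):
        tps = ["T0", "T2", "T3", "T5"]
        sample_tps = [t for t in tps for _ in range(3)]
        return tps, sample_tps

    def test_stable_high_up(self):
        tps, stp = self._tp()
        means = [[0.0] * 3 + [0.3] * 9]  # T0 low, then +0.3 at T2,T3,T5
        fam = assign_families(self._model_with_means(means), tps, stp)
        assert fam["family"].iloc[0] == "CF3"

    def test_transient_up(self):
        tps, stp = self._tp()
        means = [[0.0] * 3 + [0.3] * 3 + [0.1] * 3 + [0.0] * 3]
        fam = assign_families(self._model_with_means(means), tps, stp)
        assert fam["family"].iloc[0] == "CF1"

    def test_transient_down_mirrors(self):
        tps, stp = self._tp()
        means = [[0.0] * 3 + [-0.3] * 3 + [-0.1] * 3 + [0.0] * 3]
        fam = assign_families(self._model_with_means(means), tps, stp)
        assert fam["family"].iloc[0] == "CF2"

    def test_flat_centroid_is_weak_stable_low(self):
        tps, stp = self._tp()
        fam = assign_families(self._model_with_means([[0.2] * 12]), tps, stp)
        assert fam["family"].iloc[0] in ("CF4", "CF6")
        assert bool(fam["weak"].iloc[0])

    def test_families_partition_clusters(self):
        tps, stp = self._tp()
        rng = np.random.default_rng(10)
        means = rng.uniform(0, 0.6, size=(8, 12))
        fam = assign_families(self._model_with_means(means), tps, stp)
        assert len(fam) == 8
        assert fam["cluster"].is_unique
        assert fam["family"].isin(clustering.FAMILY_LABELS).all()


class TestHclust:
    def _de_table(self, rows):
        return pd.DataFrame(rows, columns=["feature", "contrast", "log2fc",
                                           "pvalue", "padj", "call"])

    def test_identical_profiles_merge_at_zero(self):
        y = pd.DataFrame([[0.1, 0.5, 0.2, 0.9], [0.1, 0.5, 0.2, 0.9],
                          [0.9, 0.1, 0.8, 0.1]], index=["a", "b", "c"])
        de = self._de_table([])
        linkage, _ = hclust_profiles(y, de)
        assert linkage[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_up_down_dynamic_labels(self):
        y = pd.DataFrame(np.random.default_rng(11).uniform(size=(3, 4)),
                         index=["up1", "dyn1", "dn1"])
        de = self._de_table([
            ("up1", "T0/T2", 2.0, 1e-5, 1e-4, True),
            ("dyn1", "T0/T2", 2.0, 1e-5, 1e-4, True),
            ("dyn1", "T2/T5", -2.0, 1e-5, 1e-4, True),
            ("dn1", "T3/T5", -1.0, 1e-4, 1e-3, True),
            ("dn1", "T0/T2", 3.0, 0.5, 0.9, False),  # not called: ignored
        ])
        _, labels = hclust_profiles(y, de)
        got = dict(zip(labels["feature"], labels["label"]))
        assert got == {"up1": "up", "dyn1": "dynamic", "dn1": "down"}

    def test_newick_output_parses(self):
        from Bio import Phylo

        y = pd.DataFrame(np.random.default_rng(12).uniform(size=(5, 4)),
                         index=[f"lnc{i}" for i in range(5)])
        linkage, _ = hclust_profiles(y, self._de_table([]))
        nwk = linkage_to_newick(linkage, list(y.index))
        tree = Phylo.read(std_io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == \
            sorted(y.index)


class TestTermEnrichment:
    def _hypergeom_tail(self, k, N, K, n):
        # brute-force upper tail by pmf summation
        return sum(stats.hypergeom.pmf(x, N, K, n)
                   for x in range(k, min(K, n) + 1))

    def test_matches_brute_force_tail(self):
        background = [f"g{i}" for i in range(1000)]
        cluster = background[:40]
        term_feats = background[:10] + background[500:590]  # 10 in cluster
        tm = pd.DataFrame({"feature": term_feats, "term": "GO:1"})
        out = term_enrichment(cluster, tm, background, min_entries=1, fdr=0.01)
        expected = self._hypergeom_tail(10, 1000, 100, 40)
        assert out["pvalue"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_absent_term_has_p_one(self):
        background = [f"g{i}" for i in range(100)]
        tm = pd.DataFrame({"feature": background[50:60], "term": "GO:x"})
        out = term_enrichment(background[:20], tm, background, min_entries=0)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_cluster_equal_to_background_gives_p_one(self):
        background = [f"g{i}" for i in range(60)]
        tm = pd.DataFrame({"feature": background[:30], "term": "GO:y"})
        out = term_enrichment(background, tm, background, min_entries=1)
        assert np.allclose(out["pvalue"], 1.0)

    def test_min_entries_filter_drops_sparse_terms(self):
        background = [f"g{i}" for i in range(100)]
        tm = pd.DataFrame({"feature": background[:3], "term": "GO:rare"})
        out = term_enrichment(background[:10], tm, background, min_entries=10)
        assert len(out) == 0

    def test_member_outside_background_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(["zz"], pd.DataFrame({"feature": [], "term": []}),
                            ["g0"])

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(13)
        background = [f"g{i}" for i in range(400)]
        cluster = list(rng.choice(background, size=80, replace=False))
        rows = []
        for t in range(300):
            feats = rng.choice(background, size=60, replace=False)
            rows.append(pd.DataFrame({"feature": feats, "term": f"GO:{t}"}))
        tm = pd.concat(rows, ignore_index=True)
        out = term_enrichment(cluster, tm, background, min_entries=1)
        # discrete p-values are conservative; check no gross anti-conservatism
        assert (out["pvalue"] < 0.05).mean() < 0.08
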