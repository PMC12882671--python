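"""Flavoromics statistics: scaling, differential testing, PCA, odor
activity, taste ratios, co-occurrence networks and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sonoflux.datasets import load_aa_classes, load_amino_acids
from sonoflux.flavor import (correlation_network, differential_test,
                             enrichment_test, pca, roav, scale_table,
                             umami_sweet_ratio)


def _table(rng, n_feat=10, n_samp=8):
    data = rng.lognormal(3.0, 1.0, (n_feat, n_samp))
    return pd.DataFrame(data, index=[f"f{i}" for i in range(n_feat)],
                        columns=[f"s{j}" for j in range(n_samp)])


class TestScaling:
    def test_zscore_rows_standardized(self, rng):
        out = scale_table(_table(rng), "zscore")
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_pareto_hand_value(self):
        # feature with mean 10 and SD 2 (variance 4): 14 -> (14-10)/sqrt(2)...
        # pareto divides by the square root of the SD
        vals = np.array([8.0, 10.0, 12.0, 14.0, 6.0])
        table = pd.DataFrame([vals])
        sd = vals.std(ddof=1)
        out = scale_table(table, "pareto")
        assert out.iloc[0, 3] == pytest.approx((14.0 - 10.0) / np.sqrt(sd))

    def test_log10p_of_zero_is_zero(self):
        out = scale_table(pd.DataFrame([[0.0, 9.0]]), "log10p")
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == 1.0

    def test_constant_feature_dropped_with_warning(self, rng):
        table = _table(rng)
        table.loc["f0"] = 5.0
        with pytest.warns(UserWarning):
            out = scale_table(table, "zscore")
        assert "f0" not in out.index

    def test_unknown_mode_rejected(self, rng):
        with pytest.raises(ValueError):
            scale_table(_table(rng), "rank")


class TestDifferential:
    GROUPS = (["s0", "s1", "s2"], ["s3", "s4", "s5"])

    def test_identical_groups_null(self, rng):
        table = _table(rng, n_samp=6)
        table[["s3", "s4", "s5"]] = table[["s0", "s1", "s2"]].to_numpy()
        res = differential_test(table, *self.GROUPS)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        assert not res["significant"].any()

    def test_fourfold_shift_detected(self):
        # 20 shifted features among 200, measurement CV 5%: detection >= 95%
        detected = total = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            base = r.uniform(50, 500, 200)
            a = base[:, None] * (1 + 0.05 * r.standard_normal((200, 3)))
            b = base[:, None] * (1 + 0.05 * r.standard_normal((200, 3)))
            b[:20] *= 4.0
            table = pd.DataFrame(np.hstack([a, b]),
                                 columns=[f"s{j}" for j in range(6)])
            res = differential_test(table, *self.GROUPS)
            shifted = res.iloc[:20]
            # the pseudo-count shrinks the estimate slightly below 2
            assert abs(shifted["log2fc"].mean() - 2.0) < 0.2
            detected += int(shifted["significant"].sum())
            total += 20
        assert detected / total >= 0.95

    def test_null_fdr_controlled(self):
        rates = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            table = pd.DataFrame(r.lognormal(3, 0.5, (200, 6)),
                                 columns=[f"s{j}" for j in range(6)])
            res = differential_test(table, *self.GROUPS)
            rates.append((res["q"] < 0.05).mean())
        assert np.mean(rates) <= 0.05

    def test_single_replicate_rejected(self, rng):
        table = _table(rng, n_samp=4)
        with pytest.raises(ValueError):
            differential_test(table, ["s0"], ["s1", "s2", "s3"])


class TestPCA:
    def test_fractions_sum_to_one(self, rng):
        res = pca(_table(rng))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_one_table_loads_on_first_component(self, rng):
        u = rng.normal(size=6)
        v = rng.normal(size=5)
        table = pd.DataFrame(np.outer(u, v) + 10.0)
        res = pca(table)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self, rng):
        table = _table(rng)
        res = pca(table)
        x = table.to_numpy().T
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(xc.T, bias=False))
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        frac = evals / evals.sum()
        np.testing.assert_allclose(res.explained_variance_ratio[:4], frac[:4],
                                   atol=1e-8)
        # loadings agree with eigenvectors up to sign
        for i in range(3):
            dot = abs(res.loadings.iloc[:, i] @ evecs[:, order[i]])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_loadings_orthonormal_and_reconstruction_exact(self, rng):
        table = _table(rng, n_feat=6, n_samp=5)
        res = pca(table)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        x = table.to_numpy().T
        recon = res.scores.to_numpy() @ L.T + x.mean(axis=0)
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca(pd.DataFrame(np.ones((4, 4))))


class TestROAV:
    def test_most_active_compound_anchors_at_100(self):
        out = roav([10.0, 5.0], [1.0, 1.0])
        np.testing.assert_allclose(out, [100.0, 50.0])

    def test_scale_invariant(self, rng):
        c = rng.uniform(1, 100, 6)
        ot = rng.uniform(0.1, 10, 6)
        np.testing.assert_allclose(roav(c, ot), roav(17.3 * c, ot), atol=1e-9)

    def test_all_zero_concentrations(self):
        np.testing.assert_allclose(roav([0.0, 0.0], [1.0, 2.0]), 0.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            roav([1.0], [0.0])


class TestUmamiSweetRatio:
    def test_fixture_stage_ratios(self):
        ratios = umami_sweet_ratio(load_amino_acids(), load_aa_classes())
        assert ratios["PT-G"] == pytest.approx(0.53, abs=1e-4)
        assert ratios["PT-A"] == pytest.approx(1.02, abs=1e-4)

    def test_equal_class_sums_give_unity(self):
        table = pd.DataFrame({"s": [2.0, 2.0, 2.0, 2.0]},
                             index=["Glu", "Asp", "Ala", "Thr"])
        cls = {"Glu": "umami", "Asp": "umami", "Ala": "sweet", "Thr": "sweet"}
        assert umami_sweet_ratio(table, cls)["s"] == pytest.approx(1.0)

    def test_missing_class_rejected(self):
        table = pd.DataFrame({"s": [2.0]}, index=["Glu"])
        with pytest.raises(ValueError):
            umami_sweet_ratio(table, {"Glu": "umami"})


def _brute_force_transitivity(graph):
    import networkx as nx

    nodes = list(graph)
    triangles = triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        edges = (graph.has_edge(a, b), graph.has_edge(b, c), graph.has_edge(a, c))
        if sum(edges) == 3:
            triangles += 1
        triples += sum(
            1 for centre in (a, b, c)
            if all(graph.has_edge(centre, o) for o in (a, b, c) if o != centre))
    return 3 * triangles / triples if triples else 0.0


class TestCorrelationNetwork:
    def test_perfect_pair_yields_single_unit_edge(self, rng):
        n = 10
        x = np.linspace(1, 10, n)
        data = rng.lognormal(2, 0.5, (5, n))
        data[0] = x
        data[1] = 2 * x + 1  # identical ranks -> rho = 1
        table = pd.DataFrame(data, index=[f"f{i}" for i in range(5)])
        net = correlation_network(table, rho_min=0.95)
        assert len(net.edges) == 1
        assert net.edges.iloc[0]["rho"] == pytest.approx(1.0)
        assert set(net.edges.iloc[0][["feature_i", "feature_j"]]) == {"f0", "f1"}

    def test_complete_graph_metrics(self):
        x = np.linspace(1, 8, 8)
        table = pd.DataFrame([x, 2 * x, x ** 2], index=list("abc"))
        net = correlation_network(table, rho_min=0.9)
        assert net.density == pytest.approx(1.0)
        assert net.clustering_coefficient == pytest.approx(1.0)

    def test_star_graph_has_zero_clustering(self):
        import networkx as nx

        star = nx.star_graph(4)
        assert nx.transitivity(star) == 0.0
        assert _brute_force_transitivity(star) == 0.0

    def test_transitivity_matches_brute_force_on_random_graphs(self):
        import networkx as nx

        for seed in range(5):
            g = nx.gnp_random_graph(12, 0.35, seed=seed)
            assert nx.transitivity(g) == pytest.approx(
                _brute_force_transitivity(g), abs=1e-12)

    def test_spearman_equals_rank_then_pearson_on_tie_free_data(self, rng):
        table = _table(rng, n_feat=5, n_samp=9)
        rho, _ = stats.spearmanr(table.to_numpy(), axis=1)
        ranks = np.apply_along_axis(stats.rankdata, 1, table.to_numpy())
        np.testing.assert_allclose(rho, np.corrcoef(ranks), atol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_network(_table(rng, n_samp=3))


class TestEnrichment:
    def test_hand_enumerated_hypergeometric(self):
        # universe of 8, pathway of 2, 2 hits both in the pathway:
        # p = P(X >= 2) for X ~ Hypergeom(M=8, K=2, n=2) = C(2,2)C(6,0)/C(8,2)
        universe = [f"m{i}" for i in range(8)]
        annotation = {"m0": "pw", "m1": "pw"}
        res = enrichment_test({"m0", "m1"}, annotation, universe)
        assert res.loc["pw", "p"] == pytest.approx(1.0 / 28.0, abs=1e-12)
        assert res.loc["pw", "count"] == 2

    def test_full_small_pathway_is_enriched(self):
        universe = [f"m{i}" for i in range(100)]
        annotation = {m: "pw" for m in universe[:5]}
        res = enrichment_test(set(universe[:5]), annotation, universe)
        assert res.loc["pw", "fold_enrichment"] > 1
        assert res.loc["pw", "p"] < 1e-6

    def test_uniform_null_hits_rarely_called(self):
        universe = [f"m{i}" for i in range(60)]
        annotation = {m: f"pw{i % 6}" for i, m in enumerate(universe)}
        calls = 0
        runs = 200
        rng = np.random.default_rng(0)
        for _ in range(runs):
            hits = rng.choice(universe, size=10, replace=False)
            res = enrichment_test(set(hits), annotation, universe)
            calls += int((res["q"] < 0.05).any())
        assert calls / runs <= 0.05

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test(set(), {}, [])
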