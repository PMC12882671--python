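"""Community ecology: rarefaction, diversity, Bray-Curtis, PCoA, Mantel,
Procrustes and the discriminant effect-size screen."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes as scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from sonoflux.ecology import (alpha_diversity, bray_curtis, lda_effect_size,
                              mantel, pcoa, procrustes, rarefy)


def _count_table(rng, n_taxa=12, n_samp=5, lam=40):
    data = rng.poisson(lam, (n_taxa, n_samp))
    return pd.DataFrame(data, index=[f"t{i}" for i in range(n_taxa)],
                        columns=[f"s{j}" for j in range(n_samp)])


class TestRarefy:
    def test_depth_equal_to_column_sum_is_identity(self, rng):
        table = _count_table(rng)
        col = table.columns[0]
        out = rarefy(table[[col]], int(table[col].sum()), seed=0)
        pd.testing.assert_series_equal(out[col], table[col], check_dtype=False)

    def test_preserves_depth_exactly(self, rng):
        table = _count_table(rng, lam=100)
        out = rarefy(table, 200, seed=1)
        assert (out.sum(axis=0) == 200).all()

    def test_expected_proportions_match_original(self):
        table = pd.DataFrame({"s": [600, 300, 100]})
        depth = 100
        draws = np.array([rarefy(table, depth, seed=s)["s"].to_numpy()
                          for s in range(200)], dtype=float)
        props = draws.mean(axis=0) / depth
        true = np.array([0.6, 0.3, 0.1])
        # hypergeometric mean equals the original proportion; allow 2 SE
        se = np.sqrt(true * (1 - true) / depth / 200)
        assert (np.abs(props - true) < 2 * se + 1e-12).all()

    def test_shallow_column_dropped_with_warning(self, rng):
        table = _count_table(rng)
        table["shallow"] = 0
        table.loc["t0", "shallow"] = 3
        with pytest.warns(UserWarning):
            out = rarefy(table, 50, seed=0)
        assert "shallow" not in out.columns

    def test_nonpositive_depth_rejected(self, rng):
        with pytest.raises(ValueError):
            rarefy(_count_table(rng), 0)


class TestAlphaDiversity:
    def test_single_taxon(self):
        chao1, shannon = alpha_diversity([42])
        assert chao1 == 1.0
        assert shannon == 0.0

    def test_uniform_community_shannon(self):
        _, shannon = alpha_diversity([5, 5, 5, 5])
        assert shannon == pytest.approx(np.log(4), abs=1e-12)

    def test_chao1_hand_formula(self):
        # S_obs 3, one singleton... counts (1,1,2): F1=2, F2=1
        chao1, _ = alpha_diversity([1, 1, 2])
        assert chao1 == pytest.approx(3 + 2 * 1 / (2 * 2), abs=1e-12)

    def test_matches_reference_implementation(self, rng):
        from skbio.diversity.alpha import chao1 as sk_chao1
        from skbio.diversity.alpha import shannon as sk_shannon

        counts = rng.poisson(2, 50)
        counts[0] = max(counts[0], 1)
        chao1, shannon = alpha_diversity(counts)
        assert chao1 == pytest.approx(sk_chao1(counts, bias_corrected=True))
        assert shannon == pytest.approx(sk_shannon(counts, base=np.e))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([0, 0])


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        table = pd.DataFrame({"a": [3, 5, 2], "b": [3, 5, 2]})
        assert bray_curtis(table).loc["a", "b"] == 0.0

    def test_disjoint_supports_distance_one(self):
        table = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        assert bray_curtis(table).loc["a", "b"] == 1.0

    def test_hand_arithmetic(self):
        table = pd.DataFrame({"x": [6, 4], "y": [2, 8]})
        assert bray_curtis(table).loc["x", "y"] == pytest.approx(0.4)

    def test_bounded_unit_interval(self, rng):
        table = _count_table(rng)
        d = bray_curtis(table).to_numpy()
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T, atol=1e-15)


class TestPCoA:
    def test_recovers_euclidean_configuration(self, rng):
        pts = rng.normal(size=(9, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = pcoa(d)
        coords = res.coordinates.to_numpy()[:, :2]
        assert procrustes(pts, coords).m_squared < 1e-9
        np.testing.assert_allclose(squareform(pdist(coords)),
                                   squareform(pdist(pts)), atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.ordination import pcoa as sk_pcoa

        pts = rng.normal(size=(7, 3))
        d = squareform(pdist(pts))
        res = pcoa(pd.DataFrame(d))
        ref = sk_pcoa(DistanceMatrix(d))
        np.testing.assert_allclose(
            res.fractions[:3],
            ref.proportion_explained.to_numpy()[:3], atol=1e-8)

    def test_identical_samples_coincide(self):
        d = pd.DataFrame([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = pcoa(d)
        np.testing.assert_allclose(res.coordinates.iloc[0],
                                   res.coordinates.iloc[1], atol=1e-9)

    def test_fractions_sum_to_one(self, rng):
        d = pd.DataFrame(squareform(pdist(rng.normal(size=(6, 4)))))
        res = pcoa(d)
        assert res.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame([[0.0, 1.0], [0.5, 0.0]]))


class TestMantel:
    def _random_distance(self, rng, n=10):
        return squareform(pdist(rng.normal(size=(n, 3))))

    def test_self_correlation_is_one(self, rng):
        d = self._random_distance(rng)
        r, p = mantel(d, d.copy(), n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p <= 0.05

    def test_matches_reference_statistic(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as sk_mantel

        d1 = self._random_distance(rng)
        d2 = self._random_distance(rng)
        r, _ = mantel(d1, d2, n_perm=99, seed=0)
        ref_r, _, _ = sk_mantel(DistanceMatrix(d1), DistanceMatrix(d2),
                                permutations=0)
        assert r == pytest.approx(ref_r, abs=1e-12)

    def test_invariant_to_positive_linear_rescaling(self, rng):
        d1 = self._random_distance(rng)
        d2 = self._random_distance(rng)
        r1, _ = mantel(d1, d2, n_perm=99, seed=3)
        r2, _ = mantel(d1, 4.2 * d2, n_perm=99, seed=3)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            mantel(self._random_distance(rng, 8), self._random_distance(rng, 9))


class TestProcrustes:
    def test_rotated_scaled_copy_is_exact_match(self, rng):
        x = rng.normal(size=(10, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 3.1 * x @ rot + 5.0
        res = procrustes(x, y)
        assert res.m_squared == pytest.approx(0.0, abs=1e-12)
        assert res.correlation == pytest.approx(1.0, abs=1e-9)

    def test_independent_configurations_near_one(self, rng):
        x = rng.normal(size=(300, 2))
        y = rng.normal(size=(300, 2))
        assert procrustes(x, y).m_squared > 0.9

    def test_matches_scipy_disparity(self, rng):
        for _ in range(5):
            x = rng.normal(size=(8, 3))
            y = rng.normal(size=(8, 3))
            _, _, disparity = scipy_procrustes(x, y)
            assert procrustes(x, y).m_squared == pytest.approx(disparity, abs=1e-8)

    def test_degenerate_configuration_rejected(self):
        with pytest.raises(ValueError):
            procrustes(np.zeros((5, 2)), np.random.default_rng(0).normal(size=(5, 2)))


class TestLdaEffectSize:
    def _groups(self):
        return ["lo"] * 3 + ["hi"] * 3

    def test_constant_taxon_not_significant(self):
        table = pd.DataFrame({f"s{i}": [50, 100 + i] for i in range(6)},
                             index=["flat", "varying"]).astype(float)
        res = lda_effect_size(table, self._groups())
        assert not res.loc["flat", "significant"]
        assert res.loc["flat", "constant"]

    def test_constructed_mean_gap_scores_four(self):
        # taxon A occupies 1e4 ppm-of-1e6 in 'lo' and 2e4 in 'hi':
        # class-mean gap 1e4 on the 1e6 relative scale -> score 4.0
        lo = np.array([1e4, 99e4])
        hi = np.array([2e4, 98e4])
        cols = {f"l{i}": lo for i in range(3)} | {f"h{i}": hi for i in range(3)}
        table = pd.DataFrame(cols, index=["A", "B"])
        res = lda_effect_size(table, self._groups())
        assert res.loc["A", "lda_score"] == pytest.approx(4.0, abs=1e-9)
        assert res.loc["A", "enriched_group"] == "hi"

    def test_null_permutations_rarely_significant(self):
        calls = 0
        runs = 100
        for seed in range(runs):
            r = np.random.default_rng(seed)
            table = pd.DataFrame(r.poisson(50, (15, 6)) + 1.0,
                                 columns=[f"s{i}" for i in range(6)])
            res = lda_effect_size(table, list(r.permutation(self._groups())))
            calls += int(res["significant"].any())
        assert calls / runs <= 0.05

    def test_small_group_rejected(self, rng):
        table = _count_table(rng, n_samp=4).astype(float) + 1
        with pytest.raises(ValueError):
            lda_effect_size(table, ["a", "a", "b", "b"])
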