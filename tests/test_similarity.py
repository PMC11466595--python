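import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import xsc
from xsc._rng import substream
from xsc.similarity import (PseudoProfile, choose_correlation, hallmark_correlation,
                            mantel, mantel_exact, module_scores, profile_distance,
                            pseudo_profile, species_similarity)

from conftest import make_cell_table, make_matrix


def _profile(mean, pct, types=None, genes=None, species="human"):
    mean = np.asarray(mean, dtype=float)
    types = types or [f"t{i}" for i in range(mean.shape[0])]
    genes = genes or [f"g{j}" for j in range(mean.shape[1])]
    return PseudoProfile(mean=pd.DataFrame(mean, index=types, columns=genes),
                         pct=pd.DataFrame(np.asarray(pct, float), index=types,
                                          columns=genes),
                         species=species)


class TestPseudoProfile:
    def test_mean_and_pct_arithmetic(self):
        m = make_matrix([[0.0, 2.0, 4.0], [1.0, 1.0, 1.0], [0.0, 0.0, 0.0]],
                        space="lognorm")
        t = make_cell_table(list(m.cells), ["a"] * 3)
        prof = pseudo_profile(m, t, list(m.cells))
        assert prof.mean.loc["a", "g0"] == pytest.approx(2.0)
        assert prof.pct.loc["a", "g0"] == pytest.approx(2 / 3)
        assert prof.mean.loc["a", "g1"] == 1.0 and prof.pct.loc["a", "g1"] == 1.0
        assert prof.mean.loc["a", "g2"] == 0.0 and prof.pct.loc["a", "g2"] == 0.0

    def test_only_selected_cells_used(self):
        m = make_matrix([[1.0, 1.0, 9.0]], space="lognorm")
        t = make_cell_table(list(m.cells), ["a"] * 3)
        prof = pseudo_profile(m, t, ["c0", "c1"])
        assert prof.mean.loc["a", "g0"] == 1.0

    def test_count_space_rejected(self):
        m = make_matrix([[1, 2]])
        t = make_cell_table(list(m.cells), ["a", "a"])
        with pytest.raises(ValueError, match="log-normalized"):
            pseudo_profile(m, t, list(m.cells))


class TestProfileDistance:
    def test_identical_types_have_zero_distance(self):
        p = _profile([[1, 2, 3], [1, 2, 3], [4, 0, 1]],
                     [[0.5, 1, 1], [0.5, 1, 1], [1, 0, 0.2]])
        d = profile_distance(p)
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_correlation_metric_closed_form(self):
        mean = np.array([[1.0, 2.0], [2.0, 1.0], [1.0, 1.5]])
        pct = np.array([[0.1, 0.9], [0.9, 0.1], [0.1, 0.5]])
        d = profile_distance(_profile(mean, pct), feature="both")
        feats = np.hstack([mean, pct])
        expected = 1 - np.corrcoef(feats[0], feats[1])[0, 1]
        assert d.iloc[0, 1] == pytest.approx(expected)

    def test_euclidean_metric_closed_form(self):
        mean = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        pct = np.array([[0.0, 0.0], [0.5, 0.5], [1.0, 1.0]])
        d = profile_distance(_profile(mean, pct), feature="expr", metric="euclidean")
        # per-gene z-scores of [0,1,2] are [-1.2247, 0, 1.2247]
        z = (np.array([0, 1, 2]) - 1) / np.std([0, 1, 2])
        expected = np.sqrt(2) * abs(z[0] - z[1])
        assert d.iloc[0, 1] == pytest.approx(expected)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        p = _profile(rng.random((4, 6)), rng.random((4, 6)))
        d = profile_distance(p).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)

    def test_fewer_than_three_types_rejected(self):
        p = _profile([[1, 2], [3, 4]], [[0.1, 0.2], [0.3, 0.4]])
        with pytest.raises(ValueError, match="3 cell types"):
            profile_distance(p)


def _random_distance(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.random((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return d


class TestMantel:
    def test_self_correlation_is_one(self):
        # 8 objects: the chance of drawing the identity permutation (which
        # would tie r = 1) in 99 draws is negligible
        d = _random_distance(8, 0)
        res = mantel(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        d = _random_distance(5, 1)
        d2 = 2 * d + 3
        np.fill_diagonal(d2, 0)
        assert mantel(d, d2, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_r_matches_skbio(self):
        pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel
        dA, dB = _random_distance(6, 2), _random_distance(6, 3)
        r_sk, _, _ = sk_mantel(dA, dB, method="pearson", permutations=0)
        assert mantel(dA, dB, n_perm=9, seed=0).r == pytest.approx(r_sk)

    def test_relabeling_invariance(self):
        dA, dB = _random_distance(5, 4), _random_distance(5, 5)
        perm = np.array([2, 0, 4, 1, 3])
        r0 = mantel(dA, dB, n_perm=9, seed=0).r
        r1 = mantel(dA[np.ix_(perm, perm)], dB[np.ix_(perm, perm)],
                    n_perm=9, seed=0).r
        assert r0 == pytest.approx(r1)

    def test_p_bounds(self):
        dA, dB = _random_distance(4, 6), _random_distance(4, 7)
        res = mantel(dA, dB, n_perm=199, seed=1)
        assert 1 / 200 <= res.p <= 1.0

    def test_zero_variance_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="variance"):
            mantel(d, _random_distance(4, 8), n_perm=9, seed=0)

    def test_monte_carlo_agrees_with_enumeration(self):
        dA, dB = _random_distance(4, 9), _random_distance(4, 10)
        _, p_exact = mantel_exact(dA, dB)
        res = mantel(dA, dB, n_perm=4999, seed=0)
        sigma = np.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p - p_exact) < 3 * sigma + 1 / 5000


class TestModuleScores:
    def test_constant_matrix_scores_zero(self):
        m = make_matrix(np.full((30, 5), 2.0), space="lognorm")
        sets = xsc.GeneSetCollection(sets={"S": ["g0", "g1"]})
        s = module_scores(m, sets, n_bins=5, n_ctrl=10, seed=0)
        assert np.allclose(s.to_numpy(), 0.0)

    def test_single_gene_set_matches_stepwise_recomputation(self):
        rng = np.random.default_rng(11)
        x = rng.random((20, 5)) * 3
        m = make_matrix(x, space="lognorm")
        sets = xsc.GeneSetCollection(sets={"S": ["g7"]})
        got = module_scores(m, sets, n_bins=4, n_ctrl=6, seed=3)
        # independent recomputation of the definition, step by step
        gene_mean = x.mean(axis=1)
        order = np.argsort(gene_mean, kind="stable")
        ranks = np.empty(20, dtype=int)
        ranks[order] = np.arange(20)
        bin_of = ranks * 4 // 20
        pool = np.flatnonzero(bin_of == bin_of[7])
        ctrl_rng = substream(3, "module_scores", "S")
        ctrl = ctrl_rng.choice(pool, size=6, replace=len(pool) < 6)
        expected = x[7] - x[ctrl].mean(axis=0)
        np.testing.assert_allclose(got.loc["S"].to_numpy(), expected)

    def test_cell_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.random((30, 8))
        m = make_matrix(x, space="lognorm")
        perm = rng.permutation(8)
        m2 = make_matrix(x[:, perm], cells=[f"c{j}" for j in perm], space="lognorm")
        sets = xsc.GeneSetCollection(sets={"S": ["g1", "g2", "g3"]})
        s1 = module_scores(m, sets, n_bins=5, n_ctrl=20, seed=0)
        s2 = module_scores(m2, sets, n_bins=5, n_ctrl=20, seed=0)
        np.testing.assert_allclose(s1.to_numpy()[:, perm], s2.to_numpy())

    def test_constant_shift_of_one_cell_cancels_exactly(self):
        rng = np.random.default_rng(6)
        x = rng.random((30, 6))
        x2 = x.copy()
        x2[:, 2] += 1.5  # every gene in cell 2 shifted by the same constant
        sets = xsc.GeneSetCollection(sets={"S": ["g4", "g9", "g20"]})
        s1 = module_scores(make_matrix(x, space="lognorm"), sets, seed=1,
                           n_bins=5, n_ctrl=10)
        s2 = module_scores(make_matrix(x2, space="lognorm"), sets, seed=1,
                           n_bins=5, n_ctrl=10)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_empty_after_intersection_is_error(self):
        m = make_matrix(np.ones((30, 3)), space="lognorm")
        sets = xsc.GeneSetCollection(sets={"S": ["absent"]})
        with pytest.raises(ValueError, match="empty"):
            module_scores(m, sets, n_bins=5)


class TestChooseCorrelation:
    def test_gaussian_pair_gets_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        assert scipy.stats.shapiro(x).pvalue > 0.05  # construction check
        assert choose_correlation(x, y) == "pearson"

    def test_lognormal_gets_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 2.0, size=100)
        y = rng.normal(size=100)
        assert choose_correlation(x, y) == "spearman"

    def test_decision_matches_shapiro_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            x = rng.normal(size=40) ** (rng.integers(1, 4))
            y = rng.normal(size=40)
            px, py = scipy.stats.shapiro(x).pvalue, scipy.stats.shapiro(y).pvalue
            expected = "pearson" if (px > 0.05 and py > 0.05) else "spearman"
            assert choose_correlation(x, y) == expected

    def test_constant_vector_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            method = choose_correlation([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert method == "spearman"


class TestHallmarkCorrelation:
    def test_identity_gives_r_one(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.normal(size=50))
        method, r, p = hallmark_correlation(a, a)
        assert r == pytest.approx(1.0)

    def test_rank_distorting_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = pd.Series(np.abs(rng.normal(size=60)))
        b = a ** 5  # monotone, heavily non-normal
        method, r, _ = hallmark_correlation(a, b)
        assert method == "spearman"
        assert r == pytest.approx(1.0)

    def test_pearson_matches_textbook_formula(self):
        x = np.array([1.2, 2.1, 2.9, 4.2, 5.1, 5.8, 7.1, 8.0, 8.9, 10.1])
        y = np.array([0.9, 2.2, 3.1, 3.8, 5.2, 6.1, 6.8, 8.2, 9.1, 9.8])
        method, r, _ = hallmark_correlation(pd.Series(x), pd.Series(y))
        sx, sy = x - x.mean(), y - y.mean()
        expected = (sx * sy).sum() / np.sqrt((sx ** 2).sum() * (sy ** 2).sum())
        assert method == "pearson"
        assert r == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            hallmark_correlation(pd.Series([1, 2, 3]), pd.Series([1, 2]))


class TestSpeciesSimilarity:
    def test_identical_species_r_one_min_p(self):
        rng = np.random.default_rng(7)
        mean, pct = rng.random((8, 10)), rng.random((8, 10))
        profiles = {"human": _profile(mean, pct),
                    "clone": _profile(mean, pct, species="clone")}
        out = species_similarity(profiles, n_perm=99, seed=0)
        assert len(out) == 1  # self-pairs excluded
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(1 / 100)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        p1 = _profile(rng.random((4, 5)), rng.random((4, 5)))
        p2 = _profile(rng.random((4, 6)), rng.random((4, 6)), species="m")
        with pytest.raises(ValueError, match="grid"):
            species_similarity({"human": p1, "m": p2}, n_perm=9, seed=0)
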