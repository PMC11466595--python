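import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

import xsc
from xsc.markers import (LOG2FC_THRESHOLD, bh_adjust, common_markers, find_markers,
                         log2_fold_change, passes_filter, rank_sum_test,
                         volcano_summary)

from conftest import make_cell_table, make_matrix


def _brute_force_p(a, b):
    """Independent two-sided enumeration over all label splits."""
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    na, n = len(a), len(pooled)
    mu = na * (n + 1) / 2
    obs = abs(ranks[:na].sum() - mu)
    hits = total = 0
    for idx in combinations(range(n), na):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_identical_groups_p_one(self):
        p, _ = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_all_tied_p_one(self):
        p, _ = rank_sum_test([2, 2, 2], [2, 2, 2, 2])
        assert p == 1.0

    @pytest.mark.parametrize("a,b", [
        ([1, 2, 3], [10, 11, 12]),
        ([1.5, 2.5, 9.0], [2.0, 3.0, 4.0]),
        ([1, 1, 2, 5], [3, 3, 4]),  # with ties
    ])
    def test_small_groups_match_enumeration(self, a, b):
        p, _ = rank_sum_test(a, b)
        assert p == pytest.approx(_brute_force_p(np.array(a, float),
                                                 np.array(b, float)))

    def test_label_swap_symmetry(self):
        a, b = [1.0, 4.0, 2.0, 8.0], [3.0, 9.0, 5.0]
        assert rank_sum_test(a, b)[0] == pytest.approx(rank_sum_test(b, a)[0])

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 6, 30).astype(float)
        b = rng.integers(1, 7, 25).astype(float)
        p, _ = rank_sum_test(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic").pvalue
        assert p == pytest.approx(ref)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError, match="3 observations"):
            rank_sum_test([1, 2], [3, 4, 5])


class TestLog2FoldChange:
    def test_identical_groups_zero(self):
        v = [0.5, 1.2, 2.0]
        assert log2_fold_change(v, v) == 0.0

    def test_closed_form(self):
        # back-transformed means 3 and 1 -> log2(4/2) = 1
        a = [math.log(1 + 3.0)] * 4
        b = [math.log(1 + 1.0)] * 4
        assert log2_fold_change(a, b) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 5), min_size=1, max_size=10),
           st.lists(st.floats(0, 5), min_size=1, max_size=10))
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b) == pytest.approx(-log2_fold_change(b, a))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_stepup_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_bonferroni_option(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.4], method="bonferroni"),
                                   [0.02, 0.8])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_monotone_in_p(self, ps):
        adj = bh_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _two_group_matrix(ratio, n=30, base=4.0, seed=0):
    """Log-normalized matrix whose single gene has an exact back-transformed
    fold change `ratio` between groups plus unrelated noisy genes."""
    rng = np.random.default_rng(seed)
    a_val = math.log(1 + (base * ratio + ratio - 1))   # (m_a+1)/(m_b+1) = ratio
    b_val = math.log(1 + base)
    sig = np.concatenate([np.full(n, a_val), np.full(n, b_val)])
    noise = np.abs(rng.normal(1.0, 0.05, size=(10, 2 * n)))
    x = np.vstack([sig, noise])
    genes = ["target"] + [f"n{i}" for i in range(10)]
    m = make_matrix(x, genes=genes, space="lognorm")
    t = make_cell_table(list(m.cells), ["A"] * n + ["B"] * n)
    return m, t


class TestFindMarkers:
    def test_fold_change_1p4_excluded_regardless_of_p(self):
        m, t = _two_group_matrix(1.4)
        out = find_markers(m, t, "celltype")
        assert "target" not in set(out["gene"])

    def test_strong_marker_retained_with_fields(self):
        m, t = _two_group_matrix(2.0)
        out = find_markers(m, t, "celltype")
        row = out[(out["gene"] == "target") & (out["group"] == "A")].iloc[0]
        assert row["p_adj"] < 0.05
        assert row["logFC"] == pytest.approx(1.0, abs=1e-6)
        assert row["pct_1"] > 0.25

    def test_two_group_mirror_property(self):
        m, t = _two_group_matrix(2.5, seed=3)
        out = find_markers(m, t, "celltype")
        up_a = set(out[(out["group"] == "A") & (out["logFC"] > 0)]["gene"])
        down_b = set(out[(out["group"] == "B") & (out["logFC"] < 0)]["gene"])
        assert up_a == down_b

    def test_invariant_to_gene_and_cell_order(self):
        m, t = _two_group_matrix(2.0, seed=5)
        rng = np.random.default_rng(1)
        gperm, cperm = rng.permutation(m.n_genes), rng.permutation(m.n_cells)
        m2 = xsc.CountMatrix(x=m.x[gperm][:, cperm], genes=m.genes[gperm],
                             cells=m.cells[cperm], species=m.species,
                             namespace=m.namespace, space=m.space)
        out1 = find_markers(m, t, "celltype")
        out2 = find_markers(m2, t, "celltype")
        key = lambda df: set(zip(df["gene"], df["group"]))
        assert key(out1) == key(out2)

    def test_small_group_skipped_with_warning(self, caplog):
        m, _ = _two_group_matrix(2.0)
        t = make_cell_table(list(m.cells), ["A"] * 2 + ["B"] * 58)
        with caplog.at_level("WARNING"):
            out = find_markers(m, t, "celltype")
        assert "below" in caplog.text
        assert set(out["group"]) <= {"B"}

    def test_null_filter_is_conservative(self):
        # no planted effects: the retained fraction stays below 5% on average
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = rng.negative_binomial(5, 0.5, size=(300, 80))
            m = make_matrix(counts)
            norm = xsc.normalize(m)
            t = make_cell_table(list(m.cells), ["A"] * 40 + ["B"] * 40)
            out = find_markers(norm, t, "celltype")
            fracs.append(out["gene"].nunique() / 300)
        assert np.mean(fracs) <= 0.05

    def test_planted_markers_recovered(self, recovery_analysis):
        truth = recovery_analysis["truth"]
        other = {e["gene"] for e in truth["sex_genes"]}
        for tf, tg in truth["regulons"].items():
            other |= {tf, *tg}
        planted = {(ct, g) for ct, gs in truth["markers"].items() for g in gs}
        for species in ("human", "rat"):
            out = find_markers(recovery_analysis["converted"][species],
                               recovery_analysis["tables"][species], "celltype")
            found = {(r.group, r.gene) for r in out.itertuples()
                     if r.logFC > 0 and r.gene not in other}
            tp = len(found & planted)
            assert tp / len(found) >= 0.9, species
            assert tp / len(planted) >= 0.9, species


class TestVolcanoSummary:
    def test_arithmetic(self):
        t = pd.DataFrame({
            "gene": ["g", "g", "g", "h"],
            "group": ["t1", "t2", "t3", "t1"],
            "logFC": [1.0, 2.0, -0.5, 0.7],
            "p": [0.01] * 4, "p_adj": [0.01] * 4,
            "pct_1": [0.5] * 4, "pct_2": [0.1] * 4,
        })
        summary, top = volcano_summary(t)
        row = summary[summary["gene"] == "g"].iloc[0]
        assert row["accumulated_logFC"] == pytest.approx(2.5)
        assert row["n_significant_types"] == 3
        assert top[0] == "g"

    def test_gene_without_significant_types_absent(self):
        summary, top = volcano_summary(pd.DataFrame(
            columns=["gene", "group", "logFC", "p", "p_adj", "pct_1", "pct_2"]))
        assert summary.empty and top == []

    def test_planted_female_gene_tops_fixture_volcano(self, recovery_analysis):
        truth = recovery_analysis["truth"]
        xist_like = truth["sex_genes"][0]["gene"]
        degs = find_markers(recovery_analysis["converted"]["human"],
                            recovery_analysis["tables"]["human"], "sex")
        _, top = volcano_summary(degs)
        assert top[0] == xist_like


class TestCommonMarkers:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "group", "logFC", "p", "p_adj",
                                           "pct_1", "pct_2"])

    def test_common_and_specific_sets(self):
        t1 = self._table([("g1", "ct", 2.0, 0.01, 0.01, 0.5, 0.1),
                          ("g2", "ct", 1.0, 0.01, 0.01, 0.5, 0.1)])
        t2 = self._table([("g1", "ct", 3.0, 0.01, 0.01, 0.5, 0.1),
                          ("g3", "ct", 1.0, 0.01, 0.01, 0.5, 0.1)])
        out = common_markers({"a": t1, "b": t2})
        assert out["ct"]["common"] == ["g1"]
        assert out["ct"]["specific"] == {"a": ["g2"], "b": ["g3"]}

    def test_top_common_ranked_by_min_abs_logfc(self):
        t1 = self._table([("g1", "ct", 5.0, 0, 0, 1, 0), ("g2", "ct", 2.0, 0, 0, 1, 0)])
        t2 = self._table([("g1", "ct", 1.0, 0, 0, 1, 0), ("g2", "ct", 1.9, 0, 0, 1, 0)])
        out = common_markers({"a": t1, "b": t2})
        # min |logFC|: g1 -> 1.0, g2 -> 1.9, so g2 ranks first
        assert out["ct"]["top_common"] == ["g2", "g1"]

    def test_missing_cell_type_reported(self):
        t1 = self._table([("g1", "ct1", 2, 0, 0, 1, 0)])
        t2 = self._table([("g1", "ct2", 2, 0, 0, 1, 0)])
        out = common_markers({"a": t1, "b": t2})
        assert out["_skipped_cell_types"] == ["ct1", "ct2"]


def test_filter_mask_matches_manual_thresholds():
    t = pd.DataFrame({
        "logFC": [0.5, 0.7, 0.7, -0.7],
        "p_adj": [0.01, 0.06, 0.01, 0.01],
        "pct_1": [0.5, 0.5, 0.2, 0.3],
        "pct_2": [0.1, 0.1, 0.1, 0.1],
    })
    mask = passes_filter(t)
    assert mask.tolist() == [False, False, False, True]
    assert LOG2FC_THRESHOLD == pytest.approx(math.log2(1.5))
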