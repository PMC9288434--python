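import numpy as np
import pytest
import scipy.stats

from hemorank.activity import (RankingMatrix, assign_cells, auc_score,
                               build_rankings, explore_threshold, holm_adjust,
                               kw_significance)


def rankings_from_ranks(ranks):
    ranks = np.asarray(ranks)
    genes = [f"g{i}" for i in range(ranks.shape[1])]
    cells = [f"c{i}" for i in range(ranks.shape[0])]
    return RankingMatrix(ranks=ranks, gene_ids=np.array(genes, dtype=object),
                         cell_ids=np.array(cells, dtype=object), tie_seed=0)


# ---------------------------------------------------------------------------
# Holm--Bonferroni
# ---------------------------------------------------------------------------

class TestHolm:
    def test_stepwise_worked_example(self):
        """p=(0.01, 0.03, 0.04) at alpha=0.05: 0.01 < 0.05/3 significant,
        0.03 >= 0.05/2 stops the procedure."""
        res = holm_adjust([0.01, 0.03, 0.04], alpha=0.05)
        assert list(res.significant) == [True, False, False]

    def test_all_significant(self):
        res = holm_adjust([0.001, 0.002, 0.003], alpha=0.05)
        assert res.significant.all()

    def test_matches_reference_implementation(self):
        """1000 random p-vectors agree with statsmodels' Holm flags and
        adjusted p-values."""
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            mine = holm_adjust(p, alpha=0.05)
            ref_sig, ref_adj, _, _ = multipletests(p, alpha=0.05, method="holm")
            assert list(mine.significant) == list(ref_sig)
            np.testing.assert_allclose(mine.p_adj, ref_adj, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.random(20)
        perm = rng.permutation(20)
        a = holm_adjust(p, 0.05)
        b = holm_adjust(p[perm], 0.05)
        np.testing.assert_array_equal(a.significant[perm], b.significant)
        np.testing.assert_allclose(a.p_adj[perm], b.p_adj)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            holm_adjust([0.1, 1.5])


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------

class TestRankings:
    def test_strictly_decreasing_values_rank_in_order(self):
        values = np.array([[5.0, 4, 3, 2, 1]])
        r = build_rankings(values, [f"g{i}" for i in range(5)], ["c0"], seed=0)
        assert list(r.ranks[0]) == [1, 2, 3, 4, 5]

    def test_each_row_is_a_permutation(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 4, size=(20, 30)).astype(float)
        r = build_rankings(values, [f"g{i}" for i in range(30)],
                           [f"c{i}" for i in range(20)], seed=1)
        for row in r.ranks:
            assert sorted(row) == list(range(1, 31))

    def test_ties_shuffled_reproducibly(self):
        values = np.zeros((1, 10))
        args = (values, [f"g{i}" for i in range(10)], ["c0"])
        r1 = build_rankings(*args, seed=7)
        r2 = build_rankings(*args, seed=7)
        r3 = build_rankings(*args, seed=8)
        np.testing.assert_array_equal(r1.ranks, r2.ranks)
        assert not np.array_equal(r1.ranks, r3.ranks)

    def test_zeros_ranked_after_expressed_genes(self):
        values = np.array([[0.0, 2.0, 0.0, 1.0]])
        r = build_rankings(values, list("abcd"), ["c0"], seed=0)
        assert r.ranks[0, 1] == 1 and r.ranks[0, 3] == 2
        assert set(r.ranks[0, [0, 2]]) == {3, 4}


# ---------------------------------------------------------------------------
# Recovery-curve AUC
# ---------------------------------------------------------------------------

def brute_auc(ranks_of_set, n_genes, L):
    """Exhaustive step-curve enumeration."""
    raw = 0
    for r in range(1, L + 1):
        raw += sum(1 for s in ranks_of_set if s <= r)
    k_eff = min(len(ranks_of_set), L)
    max_raw = sum(range(L - k_eff + 1, L + 1))
    return raw / max_raw if max_raw else 0.0


class TestAUC:
    def test_set_at_top_is_one(self):
        ranks = np.array([np.arange(1, 11)])
        r = rankings_from_ranks(ranks)
        auc = auc_score(r, ["g0", "g1"], top_fraction=0.5)
        assert auc[0] == 1.0

    def test_set_outside_top_is_zero(self):
        ranks = np.array([np.arange(1, 11)])
        r = rankings_from_ranks(ranks)
        auc = auc_score(r, ["g8", "g9"], top_fraction=0.5)
        assert auc[0] == 0.0

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every placement of a gene set within the ranking agrees with an
        exhaustive step-curve enumeration (batched: placements are cells)."""
        from itertools import combinations
        for n_genes in (6, 11, 20):
            base = np.arange(1, n_genes + 1)
            for L in range(1, min(10, n_genes - 1) + 1):
                top_fraction = (L + 0.5) / n_genes
                for k in range(1, min(5, n_genes) + 1):
                    placements = list(combinations(range(n_genes), k))
                    # row m places the set genes g0..g{k-1} at placement m
                    rows = np.empty((len(placements), n_genes), dtype=np.int64)
                    for m, pl in enumerate(placements):
                        rest = [i for i in range(n_genes) if i not in pl]
                        row = np.empty(n_genes, dtype=np.int64)
                        row[:k] = [base[i] for i in pl]
                        row[k:] = [base[i] for i in rest]
                        rows[m] = row
                    r = rankings_from_ranks(rows)
                    got = auc_score(r, [f"g{i}" for i in range(k)], top_fraction)
                    want = np.array([brute_auc([base[i] for i in pl], n_genes, L)
                                     for pl in placements])
                    np.testing.assert_allclose(got, want, atol=1e-12)

    def test_rank_only_dependence(self):
        """AUC is invariant to any monotone transform of expression."""
        rng = np.random.default_rng(4)
        values = rng.random((5, 40))
        genes = [f"g{i}" for i in range(40)]
        cells = [f"c{i}" for i in range(5)]
        r1 = build_rankings(values, genes, cells, seed=0)
        r2 = build_rankings(np.exp(3 * values), genes, cells, seed=0)
        np.testing.assert_array_equal(r1.ranks, r2.ranks)
        s = ["g0", "g5", "g7"]
        np.testing.assert_allclose(auc_score(r1, s, 0.25), auc_score(r2, s, 0.25))

    def test_empty_intersection_errors(self):
        r = rankings_from_ranks(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError, match="missing"):
            auc_score(r, ["nope"], 0.5)


# ---------------------------------------------------------------------------
# Threshold exploration
# ---------------------------------------------------------------------------

class TestThreshold:
    def test_bimodal_separates_modes(self):
        rng = np.random.default_rng(5)
        auc = np.concatenate([rng.normal(0.05, 0.02, 100),
                              rng.normal(0.8, 0.02, 100)])
        res = explore_threshold(auc, seed=0)
        assert res.bimodal
        assert 0.1 < res.threshold < 0.7

    def test_unimodal_falls_back_to_percentile(self):
        rng = np.random.default_rng(6)
        auc = np.abs(rng.normal(0.0, 0.005, 200))
        res = explore_threshold(auc, seed=0)
        assert not res.bimodal
        assert res.threshold == pytest.approx(np.percentile(auc, 99))

    def test_constant_input_degenerate_fallback(self):
        res = explore_threshold(np.zeros(100), seed=0)
        assert not res.bimodal

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(7)
        auc = np.concatenate([rng.normal(0.1, 0.05, 100),
                              rng.normal(0.6, 0.05, 100)])
        t1 = explore_threshold(auc, seed=3).threshold
        t2 = explore_threshold(auc, seed=3).threshold
        assert t1 == t2

    def test_too_few_cells_errors(self):
        with pytest.raises(ValueError, match="50"):
            explore_threshold(np.zeros(10), seed=0)


# ---------------------------------------------------------------------------
# Kruskal--Wallis significance
# ---------------------------------------------------------------------------

class TestKW:
    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(8)
        n_genes = 50
        ranks = np.array([rng.permutation(n_genes) + 1 for _ in range(10)])
        r = rankings_from_ranks(ranks)
        gene_set = [f"g{i}" for i in (0, 3, 7, 11, 20)]
        p, _ = kw_significance(r, gene_set, 0.05)
        idx = [0, 3, 7, 11, 20]
        rest = [i for i in range(n_genes) if i not in idx]
        for c in range(10):
            ref = scipy.stats.kruskal(ranks[c, idx], ranks[c, rest]).pvalue
            assert p[c] == pytest.approx(ref, rel=1e-9)

    def test_extreme_configuration_is_tiny(self):
        """Set genes occupying the top ranks of 1000 genes: p < 1e-10."""
        n_genes, k = 1000, 50
        ranks = np.arange(1, n_genes + 1)[None, :]
        r = rankings_from_ranks(ranks)
        gene_set = [f"g{i}" for i in range(k)]  # ranks 1..50
        p, _ = kw_significance(r, gene_set, 0.05)
        assert p[0] < 1e-10

    def test_exchangeable_null_not_significant(self):
        rng = np.random.default_rng(9)
        ranks = np.array([rng.permutation(100) + 1 for _ in range(50)])
        r = rankings_from_ranks(ranks)
        gene_set = [f"g{i}" for i in range(10)]
        _, holm = kw_significance(r, gene_set, 0.05)
        assert holm.significant.sum() <= 2

    def test_small_set_precondition(self):
        r = rankings_from_ranks(np.array([[1, 2, 3]]))
        with pytest.raises(ValueError):
            kw_significance(r, ["g0"], 0.05)


class TestAssignment:
    def test_intersection_rule(self):
        auc = np.array([0.9, 0.9, 0.1])
        p_adj = np.array([0.001, 0.5, 0.001])
        out = assign_cells(auc, 0.5, p_adj, alpha=0.05)
        assert list(out) == [True, False, False]

    def test_misaligned_inputs_error(self):
        with pytest.raises(ValueError):
            assign_cells(np.zeros(3), 0.5, np.zeros(4))
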