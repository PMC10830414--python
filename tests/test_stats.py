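import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from affopt.stats import (
    AssociationRecord,
    bh_adjust,
    bonferroni_adjust,
    boxplot_stats,
    chisq_gof,
    fisher_exact_2xk,
    fold_enrichment,
    is_gof,
    mwu_one_tailed,
    signed_logp,
)


def oracle_bh(p):
    """Textbook step-up BH: p*n/rank with cumulative min from the largest."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = n - rank_from_top
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def oracle_mwu_greater(a, b):
    """Exact one-tailed MWU p by enumerating all rank assignments."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)

    def u_stat(idx_a):
        aa = [pooled[i] for i in idx_a]
        bb = [pooled[i] for i in range(n) if i not in idx_a]
        return sum(1 for x in aa for y in bb if x > y) \
            + 0.5 * sum(1 for x in aa for y in bb if x == y)

    u_obs = u_stat(set(range(na)))
    us = [u_stat(set(c)) for c in combinations(range(n), na)]
    return sum(u >= u_obs - 1e-12 for u in us) / len(us)


class TestBh:
    def test_single_p_identity(self):
        assert bh_adjust([0.05]).tolist() == [0.05]

    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_inputs_unchanged(self):
        assert bh_adjust([0.2] * 6) == pytest.approx([0.2] * 6)

    def test_matches_textbook_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(oracle_bh(p), abs=1e-12)

    def test_monotone_when_sorted_and_capped(self):
        rng = np.random.default_rng(7)
        p = np.sort(rng.uniform(0, 1, 50))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-12) and np.all(adj <= 1)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        ([0.001], 10, [0.01]),
        ([0.5], 10, [1.0]),
        ([0.002, 0.004], 100, [0.2, 0.4]),
    ])
    def test_examples(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_m_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)


class TestSignedLogp:
    def test_examples(self):
        assert signed_logp(1.0, "up") == 0
        assert signed_logp(0.001, "down") == pytest.approx(-3)
        assert signed_logp(0.05, "up") == pytest.approx(1.301, abs=5e-4)

    def test_zero_clamped_to_floor(self):
        assert signed_logp(0.0, "up") == pytest.approx(300)

    def test_direction_required(self):
        with pytest.raises(ValueError):
            signed_logp(0.5, "none")


class TestIsGof:
    def test_truth_table(self):
        mk = lambda p, d: AssociationRecord("v", 1.0 if d == "up" else -1.0,
                                            p, p, d, 0.0)
        assert is_gof(mk(0.01, "up"))
        assert not is_gof(mk(0.01, "down"))
        assert not is_gof(mk(0.05, "up"))  # strictly below alpha


class TestMwu:
    def test_hand_example(self):
        cmp = mwu_one_tailed([3, 4, 5], [1, 2])
        assert cmp.U == 6 and cmp.p_one_tailed == pytest.approx(0.1)
        assert cmp.method == "exact"

    def test_identical_groups_not_enriched(self):
        cmp = mwu_one_tailed([1, 2, 3, 1, 2, 3], [1, 2, 3, 1, 2, 3])
        assert cmp.p_one_tailed >= 0.5

    def test_exact_path_matches_enumeration_small_inputs(self):
        """Exhaustive agreement with full permutation enumeration for all
        tie-free rank configurations with n_a + n_b <= 8."""
        for n in range(2, 9):
            for na in range(1, n):
                for idx_a in combinations(range(n), na):
                    a = [float(i) for i in idx_a]
                    b = [float(i) for i in range(n) if i not in idx_a]
                    got = mwu_one_tailed(a, b)
                    assert got.method == "exact"
                    assert got.p_one_tailed == pytest.approx(
                        oracle_mwu_greater(a, b), abs=1e-12
                    ), (a, b)

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 1.0, 100)
        b = rng.normal(0.0, 1.0, 100)
        cmp = mwu_one_tailed(a, b)
        assert cmp.method == "asymptotic"
        assert cmp.p_one_tailed < 1e-3

    def test_u_bounds(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=12), rng.normal(size=9)
        cmp = mwu_one_tailed(a, b)
        assert 0 <= cmp.U <= cmp.n_a * cmp.n_b

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_one_tailed([], [1.0])


def oracle_fisher_2x2(a, b, c, d):
    """Closed-form hypergeometric two-sided p for a 2x2 table."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    rv = sps.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-7)].sum())


class TestFisher:
    def test_diagonal_2x2(self):
        assert fisher_exact_2xk([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_homogeneous_table(self):
        assert fisher_exact_2xk([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_2x2_matches_hypergeometric_closed_form_totals_to_20(self):
        for n in range(2, 21):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        got = fisher_exact_2xk([[a, b], [c, d]])
                        want = oracle_fisher_2x2(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-9), (a, b, c, d)

    def test_2x3_matches_brute_force(self):
        table = [[2, 1, 3], [1, 4, 0]]
        # independent brute force over margin-fixed tables
        row0, col = 6, [3, 5, 3]
        lf = [math.lgamma(i + 1) for i in range(12)]
        const = lf[6] + lf[5] + sum(lf[c] for c in col) - lf[11]

        def logp(t0, t1, t2):
            cells = [t0, t1, t2, col[0] - t0, col[1] - t1, col[2] - t2]
            return const - sum(lf[x] for x in cells)

        obs = logp(2, 1, 3)
        total = sum(
            math.exp(logp(x, y, row0 - x - y))
            for x in range(col[0] + 1)
            for y in range(col[1] + 1)
            if 0 <= row0 - x - y <= col[2] and logp(x, y, row0 - x - y) <= obs + 1e-7
        )
        assert fisher_exact_2xk(table) == pytest.approx(total, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2xk([[0, 0], [1, 2]])


class TestChisqGof:
    def test_perfect_fit(self):
        stat, p = chisq_gof([10, 10], [0.5, 0.5])
        assert stat == 0 and p == pytest.approx(1.0)

    def test_total_laterality(self):
        stat, _p = chisq_gof([20, 0], [0.5, 0.5])
        assert stat == pytest.approx(20)

    def test_hand_statistic(self):
        stat, _p = chisq_gof([12, 8], [0.5, 0.5])
        assert stat == pytest.approx(0.8)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            chisq_gof([5, 5], [1.0, 0.0])


class TestFoldEnrichment:
    def test_zrs_mpra_rates(self):
        out = fold_enrichment(0.36, 0.145)
        assert out["fold_enrichment"] == pytest.approx(2.48, abs=0.005)
        assert round(out["fold_enrichment"], 1) == 2.5

    def test_all_known_optimizing_rates(self):
        assert 6 / 11 == pytest.approx(0.545, abs=5e-4)  # 55% of optimizing SNVs
        out = fold_enrichment(6 / 11, 0.145)
        assert out["fold_enrichment"] == pytest.approx(3.76, abs=0.005)
        assert round(out["fold_enrichment"], 1) == 3.8

    def test_equal_rates_unity(self):
        assert fold_enrichment(0.2, 0.2)["fold_enrichment"] == 1.0

    def test_fisher_p_from_counts(self):
        out = fold_enrichment(1.0, 0.5, counts=(2, 2, 0, 2))
        assert out["fisher_p"] == pytest.approx(1 / 3)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(0.3, 0.0)


def test_boxplot_stats_quartiles_and_whiskers():
    vals = list(range(1, 12)) + [100]  # one far outlier
    st = boxplot_stats(vals)
    assert st["n"] == 12
    assert st["q1"] < st["median"] < st["q3"]
    assert st["whisker_hi"] == 11  # outlier excluded from whisker
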