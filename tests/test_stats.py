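"""Odds ratios, exact tests, FDR and tallies against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cardiovar._round import format_ci_bound, format_or, round_half_up
from cardiovar.stats import (
    ContingencyTable,
    bh_fdr,
    binomial_two_sided,
    case_tally,
    fisher_two_sided,
    ha_odds_ratio,
    per_gene_burden,
    spearman_rho2,
    woolf_ci,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d, tol=1e-7):
    """Exhaustive minimum-likelihood two-sided Fisher for small margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    def point(x):
        return (
            math.comb(row1, x) * math.comb(n - row1, col1 - x) / math.comb(n, col1)
        )
    p_obs = point(a)
    return min(1.0, sum(point(x) for x in range(lo, hi + 1) if point(x) <= p_obs * (1 + tol)))


def binom_oracle(k, n, p0, tol=1e-7):
    probs = [math.comb(n, j) * p0**j * (1 - p0) ** (n - j) for j in range(n + 1)]
    return min(1.0, sum(p for p in probs if p <= probs[k] * (1 + tol)))


def bh_oracle(pvalues):
    """Sort-and-step BH with the running-minimum enforcement."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        q[i] = running
    return q


# ---------------------------------------------------------------------------
# odds ratio and CI
# ---------------------------------------------------------------------------


class TestHaOddsRatio:
    @pytest.mark.parametrize(
        "table,rounded",
        [
            ((4, 205, 0, 1326), 58.1),
            ((12, 197, 12, 1314), 6.7),
            ((2, 207, 0, 1326), 32.0),
            ((2, 207, 1, 1325), 10.6),
        ],
    )
    def test_published_gene_tables(self, table, rounded):
        assert round_half_up(ha_odds_ratio(ContingencyTable(*table)), 1) == rounded

    @pytest.mark.parametrize("k,n", [(1, 10), (5, 50), (0, 7)])
    def test_symmetric_table_is_unity(self, k, n):
        assert ha_odds_ratio(ContingencyTable(k, n - k, k, n - k)) == 1.0

    def test_finite_on_zero_cells(self):
        assert math.isfinite(ha_odds_ratio(ContingencyTable(0, 10, 0, 10)))

    def test_converges_to_uncorrected_for_large_cells(self):
        t = ContingencyTable(80, 500, 60, 700)
        uncorrected = t.a * t.d / (t.b * t.c)
        assert abs(ha_odds_ratio(t) - uncorrected) / uncorrected < 0.01


class TestWoolfCi:
    @pytest.mark.parametrize(
        "table,lo,hi",
        [
            ((4, 205, 0, 1326), "3.1", "1083"),
            ((2, 207, 1, 1325), "1.4", "81"),
            ((12, 197, 12, 1314), "3.0", "14.8"),
            ((2, 207, 0, 1326), "1.5", "668"),
        ],
    )
    def test_published_intervals(self, table, lo, hi):
        low, high = woolf_ci(ContingencyTable(*table))
        assert (format_ci_bound(low), format_ci_bound(high)) == (lo, hi)

    def test_symmetric_on_log_scale_for_unity_or(self):
        low, high = woolf_ci(ContingencyTable(5, 15, 5, 15))
        assert math.log(low) == pytest.approx(-math.log(high))

    def test_contains_or_and_widens_with_level(self):
        t = ContingencyTable(7, 202, 3, 1323)
        lo95, hi95 = woolf_ci(t, 0.95)
        lo99, hi99 = woolf_ci(t, 0.99)
        assert lo95 < ha_odds_ratio(t) < hi95
        assert lo99 < lo95 and hi99 > hi95


def test_ha_or_monotone_decreasing_in_control_carriers():
    ors = [
        ha_odds_ratio(ContingencyTable.from_carriers(10, 209, c, 1326))
        for c in range(0, 30)
    ]
    assert all(x > y for x, y in zip(ors, ors[1:]))


# ---------------------------------------------------------------------------
# exact tests vs enumeration
# ---------------------------------------------------------------------------


class TestFisher:
    def test_degenerate_margins(self):
        assert fisher_two_sided(ContingencyTable(0, 209, 0, 1326)) == 1.0

    def test_two_by_two_hand_enumeration(self):
        # margins (2,2)/(2,2): p(a=2)=1/6, p(1)=2/3, p(0)=1/6 -> two-sided 1/3
        assert fisher_two_sided(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 3)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(deadline=None, max_examples=150)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)

    def test_large_margins_do_not_overflow(self):
        p = fisher_two_sided(ContingencyTable(50, 4950, 20, 4980))
        assert 0.0 <= p <= 1.0


class TestBinomial:
    def test_single_draw_success(self):
        assert binomial_two_sided(1, 1, 9 / 84) == pytest.approx(9 / 84)

    def test_mode_observed_is_one(self):
        assert binomial_two_sided(1, 2, 0.5) == 1.0

    @given(st.integers(1, 20), st.data())
    @settings(deadline=None, max_examples=120)
    def test_matches_enumeration_oracle(self, n, data):
        k = data.draw(st.integers(0, n))
        p0 = data.draw(st.sampled_from([9 / 84, 0.5, 0.2]))
        assert binomial_two_sided(k, n, p0) == pytest.approx(
            binom_oracle(k, n, p0), rel=1e-9
        )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------


class TestBhFdr:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_test(self):
        assert bh_fdr([0.2]) == [pytest.approx(0.2)]

    def test_masked_entries_absent_and_m_reduced(self):
        q = bh_fdr([0.01, 0.5, 0.02], tested_mask=[True, False, True])
        assert q[1] is None
        assert q[0] == pytest.approx(0.02)  # m = 2, rank 1
        assert q[2] == pytest.approx(0.02)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=100)
    def test_matches_naive_oracle(self, pvalues):
        assert bh_fdr(pvalues) == pytest.approx(bh_oracle(pvalues))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_q_bounded_and_monotone_in_sorted_p(self, pvalues):
        q = bh_fdr(pvalues)
        assert all(0 <= qi <= 1 for qi in q)
        order = np.argsort(pvalues)
        sorted_q = [q[i] for i in order]
        assert all(x <= y + 1e-12 for x, y in zip(sorted_q, sorted_q[1:]))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_monotone_pairs(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho2(x, [2, 4, 6, 8, 10])[0] == pytest.approx(1.0)
        assert spearman_rho2(x, [10, 8, 6, 4, 2])[0] == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert spearman_rho2([1, 1, 1, 1], [1, 2, 3, 4]) == (None, None)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        rho2, _ = spearman_rho2(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        assert rho2 == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]) ** 2, abs=1e-12)


# ---------------------------------------------------------------------------
# per-gene burden and tallies
# ---------------------------------------------------------------------------


class TestPerGeneBurden:
    def test_combines_or_ci_p_and_display(self):
        results = per_gene_burden({"FKTN": (4, 0), "DSC2": (2, 0)}, 209, 1326)
        by_gene = {r.gene: r for r in results}
        assert by_gene["FKTN"].display() == "FKTN: OR = 58.1, CI: 3.1-1083"
        assert by_gene["DSC2"].display() == "DSC2: OR = 32.0, CI: 1.5-668"
        assert all(r.q is not None for r in results)

    def test_all_zero_gene_excluded_from_fdr(self):
        results = per_gene_burden({"A": (3, 1), "B": (0, 0)}, 209, 1326)
        by_gene = {r.gene: r for r in results}
        assert by_gene["B"].q is None
        assert by_gene["A"].q == pytest.approx(by_gene["A"].p)  # m reduced to 1

    def test_carrier_overflow_rejected(self):
        with pytest.raises(ValueError):
            per_gene_burden({"A": (300, 0)}, 209, 1326)

    def test_mean_estimate_recovery_and_monotonicity(self):
        """Planted carrier ORs {1, 3, 10} recovered by the corrected estimator."""
        from cardiovar.simulate import _case_rate_from_or

        rng = np.random.default_rng(42)
        r0, n_genes = 0.05, 500
        means = {}
        for theta in (1.0, 3.0, 10.0):
            p_case = _case_rate_from_or(r0, theta)
            a = rng.binomial(209, p_case, size=n_genes)
            c = rng.binomial(1326, r0, size=n_genes)
            estimates = [
                ha_odds_ratio(ContingencyTable.from_carriers(ai, 209, ci, 1326))
                for ai, ci in zip(a, c)
            ]
            means[theta] = float(np.mean(estimates))
        assert means[1.0] < means[3.0] < means[10.0]
        assert abs(means[3.0] - 3.0) / 3.0 <= 0.15


class _C:
    def __init__(self, **kw):
        self.__dict__.update(kw)

    def __getattr__(self, name):
        return False


class TestCaseTally:
    def test_published_percent_arithmetic(self):
        rows = case_tally(
            [_C(coding_positive=True)] * 77 + [_C()] * 132, 209
        )
        coding = next(r for r in rows if r["category"] == "coding_positive")
        assert coding["count"] == 77
        assert coding["pct"] == 36.8
        assert coding["pct_whole"] == "37"

    def test_one_decimal_half_up(self):
        rows = case_tally([_C(multiple_coding=True)] * 9 + [_C()] * 200, 209)
        multi = next(r for r in rows if r["category"] == "multiple_coding")
        assert multi["pct_display"] == "4.3"

    def test_zero_cases(self):
        rows = case_tally([_C()] * 209, 209)
        assert all(r["count"] == 0 and r["pct_display"] == "0.0" for r in rows)


def test_display_rounding_conventions():
    assert format_or(58.096) == "58.1"
    assert format_ci_bound(14.785) == "14.8"  # below 20: one decimal
    assert format_ci_bound(81.4) == "81"      # at/above 20: integer
    assert round_half_up(0.5) == 1.0 and round_half_up(1.5) == 2.0
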