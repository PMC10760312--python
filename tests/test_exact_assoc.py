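"""Exact 2x2 inference: Fisher p, conditional-MLE odds ratio, exact CIs.

The engine is validated three ways: against a second, independently coded
enumeration (scipy's hypergeometric distributions), against grid/bisection
oracles for the MLE and CI roots, and against the printed zero-cell rows
it must reproduce (carriers only in the case group: infinite OR with a
finite exact lower bound)."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import minimize_scalar

from homburden.exact_assoc import (
    Table2x2,
    associate,
    conditional_mle_or,
    exact_ci,
    fisher_two_sided,
)

cells = st.integers(min_value=0, max_value=40)


def scipy_fisher_oracle(t: Table2x2) -> float:
    """Second enumeration via scipy.stats.hypergeom (independent coding)."""
    lo = max(0, t.col1 - t.row2)
    hi = min(t.row1, t.col1)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, t.row1 + t.row2, t.col1, t.row1)
    obs = stats.hypergeom.pmf(t.a, t.row1 + t.row2, t.col1, t.row1)
    return float(min(1.0, pmf[pmf <= obs * (1 + 1e-7)].sum()))


def grid_mle_oracle(t: Table2x2) -> float:
    """Maximize the noncentral hypergeometric likelihood by bounded search
    seeded from a log-spaced grid over psi in 10^[-3, 3]."""
    M, n, N = t.row1 + t.row2, t.row1, t.col1

    def neg_loglik(log10_psi: float) -> float:
        return -stats.nchypergeom_fisher.logpmf(t.a, M, n, N, 10.0 ** log10_psi)

    grid = np.linspace(-3, 3, 601)
    best = grid[int(np.argmin([neg_loglik(g) for g in grid]))]
    res = minimize_scalar(neg_loglik, bounds=(best - 0.02, best + 0.02),
                          method="bounded", options={"xatol": 1e-10})
    return float(10.0 ** res.x)


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        "table, expected",
        [
            # carrier tables at the cohort's group sizes; printed to 3 decimals
            (Table2x2(3, 114, 0, 259), 0.030),
            (Table2x2(2, 55, 0, 259), 0.032),
        ],
    )
    def test_zero_cell_carrier_tables(self, table, expected):
        assert round(fisher_two_sided(table), 3) == expected

    def test_symmetric_table_is_one(self):
        assert fisher_two_sided(Table2x2(1, 1, 1, 1)) == 1.0

    @given(cells, cells, cells, cells)
    def test_agrees_with_independent_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = Table2x2(a, b, c, d)
        p = fisher_two_sided(t)
        assert p == pytest.approx(scipy_fisher_oracle(t), abs=1e-10)
        assert p == pytest.approx(stats.fisher_exact([[a, b], [c, d]])[1], abs=1e-9)

    @given(cells, cells, cells, cells)
    def test_transposition_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = Table2x2(a, b, c, d)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_two_sided(t.transpose()), abs=1e-10
        )


class TestConditionalMle:
    def test_boundary_tables(self):
        assert conditional_mle_or(Table2x2(3, 114, 0, 259))[0] == math.inf
        assert conditional_mle_or(Table2x2(0, 117, 3, 256))[0] == 0.0

    def test_exchangeable_table_is_one(self):
        psi, degenerate = conditional_mle_or(Table2x2(5, 5, 5, 5))
        assert psi == pytest.approx(1.0, abs=1e-9)
        assert not degenerate

    def test_degenerate_margins_flagged(self):
        psi, degenerate = conditional_mle_or(Table2x2(0, 5, 0, 7))
        assert (psi, degenerate) == (1.0, True)

    @pytest.mark.parametrize("table", [Table2x2(2, 3, 3, 2), Table2x2(7, 2, 4, 9),
                                       Table2x2(1, 9, 3, 12)])
    def test_matches_grid_maximization(self, table):
        assert conditional_mle_or(table)[0] == pytest.approx(
            grid_mle_oracle(table), rel=1e-6
        )

    @given(cells, cells, cells, cells)
    def test_row_swap_inverts_odds_ratio(self, a, b, c, d):
        t = Table2x2(a + 1, b, c, d + 1)  # keep support non-degenerate
        psi, deg = conditional_mle_or(t)
        psi_swapped, _ = conditional_mle_or(t.swap_rows())
        if deg or psi in (0.0, math.inf):
            return
        assert psi_swapped == pytest.approx(1 / psi, rel=1e-6)


class TestExactCi:
    def test_zero_cell_lower_bounds_match_printed_values(self):
        lo, hi = exact_ci(Table2x2(3, 114, 0, 259), 0.90)
        assert (round(lo, 2), hi) == (1.30, math.inf)
        lo2, hi2 = exact_ci(Table2x2(2, 55, 0, 259), 0.90)
        assert (round(lo2, 2), hi2) == (1.32, math.inf)

    def test_lower_bound_closed_form_root(self):
        # for (3,114|0,259) the bound solves P_psi(X >= 3) = 0.05 where the
        # support is {0..3}: direct bisection on the closed-form expression
        from math import comb

        def upper_tail(psi):
            w = [comb(117, k) * comb(259, 3 - k) * psi**k for k in range(4)]
            return w[3] / sum(w)

        lo, hi_ = 1e-6, 1e6
        for _ in range(200):
            mid = (lo + hi_) / 2
            if upper_tail(mid) < 0.05:
                lo = mid
            else:
                hi_ = mid
        assert exact_ci(Table2x2(3, 114, 0, 259), 0.90)[0] == pytest.approx(lo, rel=1e-6)

    def test_uninformative_table(self):
        assert exact_ci(Table2x2(0, 10, 0, 20)) == (0.0, math.inf)

    def test_interval_brackets_the_mle(self):
        for t in (Table2x2(8, 12, 3, 17), Table2x2(2, 3, 3, 2)):
            res = associate(t)
            assert res.ci_low <= res.or_cmle <= res.ci_high

    def test_lower_bound_monotone_in_exposed_cases(self):
        bounds = [exact_ci(Table2x2(a, 20 - a, 5, 15), 0.90)[0] for a in range(1, 8)]
        assert all(x < y for x, y in zip(bounds, bounds[1:]))

    def test_coverage_at_fixed_odds(self):
        """90% exact CIs cover the true conditional odds in >= 90% of
        simulated tables (exact inversion is conservative)."""
        psi = 2.0
        row1, row2, col1 = 25, 35, 20
        rng = np.random.default_rng(123)
        draws = stats.nchypergeom_fisher.rvs(
            row1 + row2, row1, col1, psi, size=2000, random_state=rng
        )
        covered = 0
        for a in draws:
            t = Table2x2(int(a), row1 - int(a), col1 - int(a), row2 - col1 + int(a))
            lo, hi = exact_ci(t, 0.90)
            covered += lo <= psi <= hi
        assert covered / 2000 >= 0.90
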