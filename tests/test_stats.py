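"""Exact-test implementations against independent enumeration oracles."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cistrans.stats import (
    bh_fdr,
    binomial_exact_test,
    fisher_exact_2x2,
    fisher_exact_rxc,
)


def binom_oracle_half(x: int, n: int) -> float:
    """Exact two-sided binomial p at p0=1/2 by integer-weight enumeration."""
    w = [comb(n, k) for k in range(n + 1)]
    return float(Fraction(sum(wk for wk in w if wk <= w[x]), 2**n))


def fisher22_oracle(a, b, c, d) -> float:
    """Exact Fisher two-sided p by integer-weight hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ws = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    return float(Fraction(sum(w for w in ws.values() if w <= ws[a]), comb(n, c1)))


def fh_oracle_2xc(table) -> float:
    """Exact Freeman-Halton p for a 2xc table by integer-weight enumeration."""
    t = np.asarray(table, dtype=int)
    row1 = t[0].sum()
    cols = t.sum(axis=0)
    n = int(t.sum())

    def weight(x):
        return math.prod(comb(int(cj), int(xj)) for cj, xj in zip(cols, x))

    w_obs = weight(t[0])
    total = 0
    if len(cols) == 2:
        candidates = (
            (x0, row1 - x0)
            for x0 in range(max(0, row1 - cols[1]), min(row1, cols[0]) + 1)
        )
    else:
        candidates = (
            (x0, x1, row1 - x0 - x1)
            for x0 in range(min(row1, cols[0]) + 1)
            for x1 in range(
                max(0, row1 - x0 - cols[2]), min(row1 - x0, cols[1]) + 1
            )
        )
    for x in candidates:
        w = weight(x)
        if w <= w_obs:
            total += w
    return float(Fraction(total, comb(n, int(row1))))


class TestBinomialExact:
    def test_matches_enumeration_for_all_small_n(self):
        for n in range(1, 31):
            for x in range(n + 1):
                expected = binom_oracle_half(x, n)
                assert binomial_exact_test(x, n) == pytest.approx(
                    expected, abs=1e-12
                ), (x, n)

    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (10, 10, 0.001953125),  # 2 * (1/2)**10
            (5, 10, 1.0),  # the mode of the symmetric null
            (3, 12, binom_oracle_half(3, 12)),
        ],
    )
    def test_reference_values(self, x, n, expected):
        assert binomial_exact_test(x, n) == pytest.approx(expected, abs=1e-12)

    def test_asymmetric_null_matches_float_enumeration(self):
        p0 = 0.3
        for x, n in [(0, 12), (7, 12), (12, 12), (4, 9)]:
            pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
            expected = pmf[pmf <= pmf[x] * (1 + 1e-7)].sum()
            assert binomial_exact_test(x, n, p0) == pytest.approx(expected, abs=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            binomial_exact_test(5, 4)
        with pytest.raises(ValueError):
            binomial_exact_test(1, 0)
        with pytest.raises(ValueError):
            binomial_exact_test(1, 2, p0=1.0)


def _all_tables_2x2(max_total):
    for n in range(1, max_total + 1):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    yield a, b, c, n - a - b - c


class TestFisher2x2:
    def test_exhaustive_small_totals(self):
        for a, b, c, d in _all_tables_2x2(18):
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher22_oracle(a, b, c, d), abs=1e-12
            ), (a, b, c, d)

    def test_sampled_totals_up_to_60(self):
        rng = np.random.default_rng(2024)
        for _ in range(400):
            n = int(rng.integers(19, 61))
            cuts = np.sort(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                fisher22_oracle(a, b, c, d), abs=1e-12
            ), (a, b, c, d)

    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((3, 0, 0, 3), 0.1),  # 2 * (1/20)
        ],
    )
    def test_reference_values(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, abs=1e-12)

    def test_extreme_table_is_tiny(self):
        assert fisher_exact_2x2(36, 16, 2, 50) < 1e-6

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            cells = rng.integers(0, 30, size=4)
            if cells.sum() == 0:
                continue
            ours = fisher_exact_2x2(*cells)
            theirs = sps.fisher_exact(cells.reshape(2, 2))[1]
            assert ours == pytest.approx(theirs, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)


class TestFreemanHalton:
    def test_2x3_exhaustive_small_totals(self):
        for n in range(1, 13):
            rng = np.random.default_rng(n)
            for _ in range(30):
                cells = rng.multinomial(n, [1 / 6] * 6).reshape(2, 3)
                assert fisher_exact_rxc(cells) == pytest.approx(
                    fh_oracle_2xc(cells), abs=1e-12
                ), cells.tolist()

    def test_2x3_sampled_totals_up_to_60(self):
        rng = np.random.default_rng(99)
        for _ in range(250):
            n = int(rng.integers(13, 61))
            probs = rng.dirichlet(np.ones(6))
            cells = rng.multinomial(n, probs).reshape(2, 3)
            assert fisher_exact_rxc(cells) == pytest.approx(
                fh_oracle_2xc(cells), abs=1e-12
            ), cells.tolist()

    def test_2x2_subcase_equals_fisher_2x2(self):
        for a, b, c, d in _all_tables_2x2(14):
            assert fisher_exact_rxc([[a, b], [c, d]]) == pytest.approx(
                fisher_exact_2x2(a, b, c, d), abs=1e-12
            ), (a, b, c, d)

    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[10, 10, 10], [10, 10, 10]], 1.0),
            ([[3, 0], [0, 3]], 0.1),
        ],
    )
    def test_reference_values(self, table, expected):
        assert fisher_exact_rxc(table) == pytest.approx(expected, abs=1e-12)

    def test_transgressive_sterile_vs_fertile_table(self):
        assert fisher_exact_rxc([[36, 16], [2, 50]]) < 0.001

    def test_size_and_total_caps(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError):
            fisher_exact_rxc(np.ones((2, 4), dtype=int))
        with pytest.raises(ValueError):
            fisher_exact_rxc([[150, 0, 0], [0, 150, 0]])

    def test_degenerate_single_row(self):
        assert fisher_exact_rxc([[4, 5, 6]]) == 1.0


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ],
    )
    def test_reference_values(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_q_dominates_p_and_is_monotone_in_rank(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
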