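"""Exact tests and multiple-testing correction for allele-specific expression.

The three per-gene tests of the ASE pipeline (parental imbalance, hybrid
allelic imbalance, parental-ratio vs hybrid-ratio) are exact small-sample
tests: a two-sided binomial exact test for the first two and Fisher's exact
test for the third.  Group-level comparisons of inheritance spectra use the
Freeman-Halton extension of Fisher's test to 2x3 tables.  All two-sided
p-values follow the minimum-likelihood convention: the p-value is the sum of
the probabilities of every outcome no more probable than the observed one.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "binomial_exact_test",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "bh_fdr",
]

# Relative slack when comparing outcome probabilities for two-sided inclusion;
# exact ties (e.g. the mirror outcome under a symmetric null) must be included
# despite floating-point noise.  Same convention as R's fisher.test.
_REL_SLACK = math.log1p(1e-7)


def binomial_exact_test(x: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for ``x`` successes out of ``n``.

    Minimum-likelihood two-sided convention (the scipy default): sums P(k)
    over all k whose probability does not exceed P(x).

    Parameters
    ----------
    x : observed successes, ``0 <= x <= n``.
    n : number of trials, positive.
    p0 : null success probability, in (0, 1).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must lie in [0, n]; got x={x}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    return float(_sps.binomtest(int(x), int(n), p0).pvalue)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Enumerates the hypergeometric distribution over the fixed margins and
    sums the probabilities of all tables no more probable than the observed
    one.
    """
    cells = (a, b, c, d)
    if any(v < 0 for v in cells):
        raise ValueError(f"cell counts must be non-negative, got {cells}")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table has no sampling distribution")
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    logpmf = _sps.hypergeom.logpmf(support, n, row1, col1)
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + _REL_SLACK
    from scipy.special import logsumexp

    return float(min(1.0, math.exp(logsumexp(logpmf[keep]))))


def _log_multinomial_table(cells, log_margin_term):
    return log_margin_term - sum(math.lgamma(v + 1) for v in cells)


def fisher_exact_rxc(table, max_total: int = 200) -> float:
    """Freeman-Halton exact p-value for an r x c table, r <= 2 and c <= 3.

    Enumerates every table with the observed margins and sums the
    probabilities of those no more probable than the observed table.  The
    enumeration is exact, so table totals are capped (default 200); larger
    tables are rejected rather than approximated.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    r, c = t.shape
    if r > 2 or c > 3:
        raise ValueError(f"unsupported table shape {t.shape}; at most 2x3")
    total = int(t.sum())
    if total == 0:
        raise ValueError("all-zero table has no sampling distribution")
    if total > max_total:
        raise ValueError(
            f"table total {total} exceeds the enumeration cap {max_total}"
        )
    if r == 1 or c == 1:
        return 1.0  # margins determine the table uniquely

    row = t.sum(axis=1)
    col = t.sum(axis=0)
    log_margin = (
        sum(math.lgamma(v + 1) for v in row)
        + sum(math.lgamma(v + 1) for v in col)
        - math.lgamma(total + 1)
    )
    log_obs = _log_multinomial_table(t.ravel(), log_margin)

    logps = []
    if c == 2:
        for x0 in range(max(0, row[0] - col[1]), min(row[0], col[0]) + 1):
            x1 = row[0] - x0
            cells = (x0, x1, col[0] - x0, col[1] - x1)
            logps.append(_log_multinomial_table(cells, log_margin))
    else:  # c == 3
        for x0 in range(min(row[0], col[0]) + 1):
            rem = row[0] - x0
            for x1 in range(max(0, rem - col[2]), min(rem, col[1]) + 1):
                x2 = rem - x1
                cells = (x0, x1, x2, col[0] - x0, col[1] - x1, col[2] - x2)
                logps.append(_log_multinomial_table(cells, log_margin))
    logps = np.array(logps)
    from scipy.special import logsumexp

    keep = logps <= log_obs + _REL_SLACK
    return float(min(1.0, math.exp(logsumexp(logps[keep]))))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
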