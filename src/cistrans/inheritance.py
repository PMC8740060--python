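"""Inheritance mode of hybrid expression and group-spectrum comparisons.

A gene's hybrid expression relative to the two parents is classified from
two pairwise differential-expression calls (hybrid vs each parent):

* transgressive_up / transgressive_down — significantly above / below both
  parents;
* non_differential — significant versus neither parent;
* additive — the exhaustive residual: significant versus at least one
  parent without being transgressive (intermediate expression).

Production runs consume external DE-call tables (e.g. a DESeq2 + edgeR
consensus at FDR 5% and |lfc| > 1).  :func:`simple_pairwise_test` is a
built-in stand-in — Welch's t on log2(count + 1) — so synthetic end-to-end
runs need no external caller.  Spectra of two hybrid groups are compared
with the Freeman-Halton exact test, either three-way (transgressive /
additive / non-differential) or collapsed to transgressive-vs-rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import fisher_exact_rxc

__all__ = [
    "MODES",
    "PairwiseDeCall",
    "InheritanceCall",
    "simple_pairwise_test",
    "classify_inheritance",
    "classify_inheritance_table",
    "compare_inheritance_spectra",
]

MODES = ("transgressive_up", "transgressive_down", "additive", "non_differential")


@dataclass(frozen=True)
class PairwiseDeCall:
    """One pairwise differential-expression call (first group over second)."""

    gene_id: str
    comparison: str
    lfc: float
    pvalue: float
    significant: bool


@dataclass(frozen=True)
class InheritanceCall:
    gene_id: str
    mode: str


def simple_pairwise_test(
    counts_a,
    counts_b,
    gene_id: str = "",
    comparison: str = "",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> PairwiseDeCall:
    """Welch's t-test on log2(count + 1) replicate values.

    Significant iff p < ``alpha`` and |lfc| > ``lfc_threshold``, where lfc
    is the difference of mean log2(count + 1), first group over second.
    """
    a = np.log2(np.asarray(counts_a, dtype=float) + 1.0)
    b = np.log2(np.asarray(counts_b, dtype=float) + 1.0)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 replicates per group")
    lfc = float(a.mean() - b.mean())
    if np.allclose(a.var(), 0.0) and np.allclose(b.var(), 0.0):
        p = 1.0 if np.isclose(lfc, 0.0) else 0.0
    else:
        p = float(_sps.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    significant = p < alpha and abs(lfc) > lfc_threshold
    return PairwiseDeCall(gene_id, comparison, lfc, p, significant)


def classify_inheritance(
    call_vs_ppse: PairwiseDeCall, call_vs_pbog: PairwiseDeCall
) -> InheritanceCall:
    """Combine the two hybrid-vs-parent calls into an inheritance mode."""
    if call_vs_ppse.gene_id != call_vs_pbog.gene_id:
        raise ValueError(
            f"gene_id mismatch: {call_vs_ppse.gene_id!r} vs {call_vs_pbog.gene_id!r}"
        )
    s1, s2 = call_vs_ppse.significant, call_vs_pbog.significant
    if s1 and s2 and call_vs_ppse.lfc > 0 and call_vs_pbog.lfc > 0:
        mode = "transgressive_up"
    elif s1 and s2 and call_vs_ppse.lfc < 0 and call_vs_pbog.lfc < 0:
        mode = "transgressive_down"
    elif not s1 and not s2:
        mode = "non_differential"
    else:
        mode = "additive"
    return InheritanceCall(call_vs_ppse.gene_id, mode)


def classify_inheritance_table(
    hybrid: pd.DataFrame,
    parent_pse: pd.DataFrame,
    parent_bog: pd.DataFrame,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene of replicate count matrices (genes x replicates).

    The three matrices must share their gene index.  Returns a DataFrame
    with gene_id, mode, and the two hybrid-vs-parent lfc values.
    """
    if not (hybrid.index.equals(parent_pse.index) and hybrid.index.equals(parent_bog.index)):
        raise ValueError("count matrices must share the same gene index")
    rows = []
    for gene in hybrid.index:
        c1 = simple_pairwise_test(
            hybrid.loc[gene], parent_pse.loc[gene], gene, "H_vs_Ppse", alpha, lfc_threshold
        )
        c2 = simple_pairwise_test(
            hybrid.loc[gene], parent_bog.loc[gene], gene, "H_vs_Pbog", alpha, lfc_threshold
        )
        call = classify_inheritance(c1, c2)
        rows.append((gene, call.mode, c1.lfc, c2.lfc))
    return pd.DataFrame(rows, columns=["gene_id", "mode", "lfc_vs_ppse", "lfc_vs_pbog"])


def _spectrum(calls, collapse: str):
    modes = [c.mode if isinstance(c, InheritanceCall) else str(c) for c in calls]
    bad = set(modes) - set(MODES)
    if bad:
        raise ValueError(f"unknown inheritance modes: {sorted(bad)}")
    trans = sum(m.startswith("transgressive") for m in modes)
    if collapse == "transgressive-vs-rest":
        return [trans, len(modes) - trans]
    return [
        trans,
        sum(m == "additive" for m in modes),
        sum(m == "non_differential" for m in modes),
    ]


def compare_inheritance_spectra(
    group_a, group_b, collapse: str = "three-way"
) -> tuple[pd.DataFrame, float]:
    """Exact comparison of two groups' inheritance-mode spectra.

    ``collapse`` is ``"three-way"`` (transgressive / additive /
    non-differential; transgressive_up and _down are pooled) or
    ``"transgressive-vs-rest"`` (2x2).  Accepts iterables of
    :class:`InheritanceCall` or of mode strings.  Returns the contingency
    table and the Freeman-Halton exact p-value.
    """
    if collapse not in ("three-way", "transgressive-vs-rest"):
        raise ValueError(f"unknown collapse mode {collapse!r}")
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    rows = [_spectrum(group_a, collapse), _spectrum(group_b, collapse)]
    if collapse == "transgressive-vs-rest":
        cols = ["transgressive", "other"]
    else:
        cols = ["transgressive", "additive", "non_differential"]
    table = pd.DataFrame(rows, index=["group_a", "group_b"], columns=cols)
    p = fisher_exact_rxc(table.to_numpy())
    return table, p
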