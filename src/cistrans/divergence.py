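"""Six-category cis/trans regulatory-divergence classification.

Three exact tests per gene on the depth-adjusted allele-origin totals:

1. parental imbalance — binomial exact test of P_pse against P_pse + P_bog;
2. hybrid allelic imbalance — binomial exact test of H_pse against
   H_pse + H_bog (both alleles share one trans environment, so imbalance
   here is a cis signal);
3. ratio shift — Fisher's exact test of the 2x2 table
   [[P_pse, P_bog], [H_pse, H_bog]].

Each test family is Benjamini-Hochberg corrected across genes and the three
significance flags map onto the categories:

    (-, -, -) conserved      (+, +, -) cis_only      (+, -, +) trans_only
    (+, +, +) cis_and_trans  (-, +, +) compensatory  otherwise ambiguous

cis_only, cis_and_trans and compensatory are pooled into a broad
"cis effects" group.  The significance threshold defaults to q < 0.005
(0.5%); pass ``alpha=0.05`` for the conventional 5%.
"""

from __future__ import annotations

import math

import pandas as pd

from .ase import CLASSES
from .stats import bh_fdr, binomial_exact_test, fisher_exact_2x2

__all__ = [
    "CATEGORY_TABLE",
    "CIS_EFFECT_CATEGORIES",
    "classify_regulatory_divergence",
    "summarize_cis_effects",
]

CATEGORY_TABLE = {
    (False, False, False): "conserved",
    (True, True, False): "cis_only",
    (True, False, True): "trans_only",
    (True, True, True): "cis_and_trans",
    (False, True, True): "compensatory",
}

CIS_EFFECT_CATEGORIES = frozenset({"cis_only", "cis_and_trans", "compensatory"})


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_regulatory_divergence(
    counts: pd.DataFrame, alpha: float = 0.005
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the three exact tests, FDR-correct, and assign categories.

    Parameters
    ----------
    counts : DataFrame with gene_id and the four depth-adjusted classes
        P_pse, P_bog, H_pse, H_bog (real values are rounded half-up).
    alpha : significance threshold on the q-values.

    Returns
    -------
    tests : per-gene p, q and significance flag for each of the three tests.
    calls : per-gene category and the broad cis_effect flag.
    """
    required = ["gene_id", *CLASSES]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"count table is missing columns {missing}")
    if len(counts) == 0:
        raise ValueError("empty count table")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")

    p_parent, p_hybrid, p_ratio = [], [], []
    for row in counts.itertuples():
        pp, pb = _round_half_up(row.P_pse), _round_half_up(row.P_bog)
        hp, hb = _round_half_up(row.H_pse), _round_half_up(row.H_bog)
        p_parent.append(binomial_exact_test(pp, pp + pb))
        p_hybrid.append(binomial_exact_test(hp, hp + hb))
        p_ratio.append(fisher_exact_2x2(pp, pb, hp, hb))

    tests = pd.DataFrame({"gene_id": counts["gene_id"].to_numpy()})
    for name, p in [("parent", p_parent), ("hybrid", p_hybrid), ("ratio", p_ratio)]:
        q = bh_fdr(p)
        tests[f"p_{name}"] = p
        tests[f"q_{name}"] = q
        tests[f"sig_{name}"] = q < alpha

    categories = [
        CATEGORY_TABLE.get((s1, s2, s3), "ambiguous")
        for s1, s2, s3 in zip(
            tests["sig_parent"], tests["sig_hybrid"], tests["sig_ratio"]
        )
    ]
    calls = pd.DataFrame(
        {
            "gene_id": tests["gene_id"],
            "category": categories,
            "cis_effect": [c in CIS_EFFECT_CATEGORIES for c in categories],
        }
    )
    return tests, calls


def summarize_cis_effects(calls: pd.DataFrame) -> tuple[float, pd.Series]:
    """Category tallies and the fraction of genes with any cis effect."""
    if len(calls) == 0:
        raise ValueError("empty call table")
    tallies = calls["category"].value_counts()
    fraction = float(calls["cis_effect"].sum()) / len(calls)
    return fraction, tallies
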