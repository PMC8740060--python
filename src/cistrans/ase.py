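"""Fixed diagnostic SNPs, parent-of-origin counting, filters, depth adjustment.

A SNP is diagnostic between the subspecies when each parent shows a single
allele at the site (tri-allelic parents are rejected), the two alleles
differ, and each is supported by at least ``min_support`` reads summed over
that subspecies' samples.  Hybrid reads are then assigned to a parent of
origin by the allele they carry at these fixed SNPs, summed per gene across
sites and replicates into the four classes P_pse, P_bog, H_pse, H_bog.
Genes with fewer than ``min_reads`` summed parental reads are dropped.
Finally each class is rescaled to the smallest class library and zeros are
replaced by 1 so the exact tests are defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .distribution import GeneLocus

__all__ = [
    "FixedSnp",
    "call_fixed_snps",
    "aggregate_gene_counts",
    "adjust_depth",
    "CLASSES",
]

CLASSES = ("P_pse", "P_bog", "H_pse", "H_bog")

_OBS_COLS = ["chromosome", "position", "sample", "subspecies", "allele", "count"]
_AC_COLS = ["chromosome", "position", "sample", "group", "allele", "count"]
GROUPS = ("parent_pse", "parent_bog", "hybrid")


@dataclass(frozen=True)
class FixedSnp:
    chromosome: str
    position: int
    allele_pse: str
    allele_bog: str
    support_pse: int
    support_bog: int


def _check_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def call_fixed_snps(
    observations: pd.DataFrame, min_support: int = 3
) -> list[FixedSnp]:
    """Call fixed diagnostic SNPs from parental per-site allele observations.

    ``observations`` columns: chromosome, position, sample, subspecies
    (pse|bog), allele, count.  A site is emitted iff each subspecies shows
    exactly one allele (with positive reads), the alleles differ, and each
    has >= ``min_support`` reads summed across that subspecies' samples.
    """
    _check_columns(observations, _OBS_COLS, "observation table")
    obs = observations.loc[observations["count"] > 0].copy()
    bad = set(obs["subspecies"].unique()) - {"pse", "bog"}
    if bad:
        raise ValueError(f"unknown subspecies labels: {sorted(bad)}")
    if (obs["position"] < 1).any():
        raise ValueError("positions are 1-based and must be >= 1")
    dup = obs.duplicated(["chromosome", "position", "sample", "allele"])
    if dup.any():
        rows = obs.loc[dup, ["chromosome", "position", "sample", "allele"]]
        raise ValueError(
            "conflicting duplicate observation records at "
            + "; ".join(
                f"{r.chromosome}:{r.position} {r.sample} {r.allele}"
                for r in rows.itertuples()
            )
        )

    support = (
        obs.groupby(["chromosome", "position", "subspecies", "allele"])["count"]
        .sum()
        .reset_index()
    )
    snps = []
    for (chrom, pos), site in support.groupby(["chromosome", "position"], sort=True):
        by_sub = {
            sub: dict(zip(grp["allele"], grp["count"]))
            for sub, grp in site.groupby("subspecies")
        }
        if set(by_sub) != {"pse", "bog"}:
            continue  # site unobserved in one parent
        if len(by_sub["pse"]) != 1 or len(by_sub["bog"]) != 1:
            continue  # polymorphic (or tri-allelic) within a parent
        (a_pse, n_pse), = by_sub["pse"].items()
        (a_bog, n_bog), = by_sub["bog"].items()
        if a_pse == a_bog:
            continue
        if n_pse < min_support or n_bog < min_support:
            continue
        snps.append(FixedSnp(chrom, int(pos), a_pse, a_bog, int(n_pse), int(n_bog)))
    return snps


def _locate(snp: FixedSnp, loci) -> GeneLocus | None:
    hits = [
        l
        for l in loci
        if l.chromosome == snp.chromosome and l.start <= snp.position <= l.end
    ]
    if len(hits) > 1:
        raise ValueError(
            f"SNP {snp.chromosome}:{snp.position} overlaps multiple loci: "
            + ", ".join(l.gene_id for l in hits)
        )
    return hits[0] if hits else None


def aggregate_gene_counts(
    snps: list[FixedSnp],
    allele_counts: pd.DataFrame,
    loci,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Assign reads at fixed SNPs to parent of origin and sum per gene.

    ``allele_counts`` columns: chromosome, position, sample, group
    (parent_pse | parent_bog | hybrid), allele, count.  Parental reads count
    toward P_pse / P_bog when the sample's own subspecies allele matches the
    SNP; hybrid reads are split into H_pse / H_bog by allele identity.
    Reads carrying neither diagnostic allele are ignored.  Genes with
    P_pse + P_bog < ``min_reads`` are dropped.  SNPs outside every locus are
    ignored; a SNP inside two loci is an error.
    """
    _check_columns(allele_counts, _AC_COLS, "allele-count table")
    bad = set(allele_counts["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown sample groups: {sorted(bad)}")

    site_index: dict[tuple[str, int], tuple[str, FixedSnp]] = {}
    for snp in snps:
        gene = _locate(snp, loci)
        if gene is not None:
            site_index[(snp.chromosome, snp.position)] = (gene.gene_id, snp)

    totals: dict[str, dict[str, int]] = {}
    for row in allele_counts.itertuples():
        key = (row.chromosome, row.position)
        if key not in site_index:
            continue
        gene_id, snp = site_index[key]
        cls = None
        if row.group == "parent_pse" and row.allele == snp.allele_pse:
            cls = "P_pse"
        elif row.group == "parent_bog" and row.allele == snp.allele_bog:
            cls = "P_bog"
        elif row.group == "hybrid":
            if row.allele == snp.allele_pse:
                cls = "H_pse"
            elif row.allele == snp.allele_bog:
                cls = "H_bog"
        if cls is None:
            continue
        gene = totals.setdefault(gene_id, dict.fromkeys(CLASSES, 0))
        gene[cls] += int(row.count)

    rows = []
    for gene_id in sorted(totals):
        t = totals[gene_id]
        parental = t["P_pse"] + t["P_bog"]
        if parental < min_reads:
            continue
        rows.append((gene_id, t["P_pse"], t["P_bog"], t["H_pse"], t["H_bog"], parental))
    return pd.DataFrame(
        rows, columns=["gene_id", "P_pse", "P_bog", "H_pse", "H_bog", "raw_total"]
    )


def adjust_depth(
    counts: pd.DataFrame, class_totals: dict[str, float]
) -> pd.DataFrame:
    """Rescale each class to the smallest class library; zeros become 1.

    Each class count is multiplied by (smallest class total / its class
    total), rounded half-up to an integer; any resulting 0 is replaced by 1
    so downstream exact tests are always defined.  Gene order is preserved.
    """
    _check_columns(counts, ["gene_id", *CLASSES], "count table")
    missing = [c for c in CLASSES if c not in class_totals]
    if missing:
        raise ValueError(f"class_totals missing {missing}")
    if any(class_totals[c] <= 0 for c in CLASSES):
        raise ValueError("class library totals must be positive")

    smallest = min(class_totals[c] for c in CLASSES)
    out = counts.copy()
    for c in CLASSES:
        scale = smallest / class_totals[c]
        scaled = (out[c] * scale).map(lambda v: int(math.floor(v + 0.5)))
        out[c] = scaled.where(scaled > 0, 1)
    return out
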