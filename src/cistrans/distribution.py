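"""Chromosomal distribution of target genes: densities, chi-square, clusters.

Operates on gene loci (1-based inclusive spans; spans supplied high-to-low
are normalised with the strand recorded as minus).  Densities are targets per
megabase per chromosome with a pooled autosome entry; the goodness-of-fit
test compares observed per-chromosome counts to a length-proportional or
uniform expectation; clustering chains neighbouring genes whose closest-edge
gap does not exceed a threshold (default 5500 bp, i.e. "approximately 5 kb"
with enough slack to keep a 5.2 kb pair together).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _sps

__all__ = [
    "GeneLocus",
    "ChiSquareResult",
    "ClusterCall",
    "gene_gap",
    "detect_clusters",
    "chromosome_density",
    "chisq_distribution_test",
]


def _round_half_up(x: float, decimals: int = 0) -> float:
    f = 10**decimals
    return math.floor(x * f + 0.5) / f


@dataclass(frozen=True)
class GeneLocus:
    """A gene span; ``start <= end`` after canonicalisation."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "?"

    def __post_init__(self):
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.gene_id}: coordinates are 1-based positive")
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start > end; use GeneLocus.from_span to "
                "canonicalise an oriented span"
            )
        if self.strand not in ("+", "-", "?"):
            raise ValueError(f"{self.gene_id}: strand must be +, - or ?")

    @classmethod
    def from_span(cls, gene_id: str, chromosome: str, a: int, b: int) -> "GeneLocus":
        """Build from an oriented span; ``a > b`` means minus strand."""
        if a <= b:
            return cls(gene_id, chromosome, a, b, "+")
        return cls(gene_id, chromosome, b, a, "-")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class ClusterCall:
    """A maximal chain of same-chromosome genes with small inter-gene gaps."""

    gene_ids: tuple[str, ...]
    chromosome: str
    gaps: tuple[int, ...]  # consecutive closest-edge gaps, len(gene_ids) - 1

    @property
    def gap_bp(self) -> int:
        return max(self.gaps)


def gene_gap(a: GeneLocus, b: GeneLocus) -> int:
    """Closest-edge distance in bp between two loci on one chromosome.

    Overlapping or adjacent spans give 0.
    """
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"{a.gene_id} ({a.chromosome}) and {b.gene_id} ({b.chromosome}) "
            "are on different chromosomes"
        )
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end)


def detect_clusters(loci, max_gap: int = 5500) -> list[ClusterCall]:
    """Chain genes within ``max_gap`` bp of their neighbour into clusters.

    Per chromosome, genes sorted by start are linked whenever the
    closest-edge gap to the previous gene is <= ``max_gap``; maximal chains
    of two or more genes are reported (singletons are not).
    """
    loci = list(loci)
    seen = set()
    for l in loci:
        if l.gene_id in seen:
            raise ValueError(f"duplicate gene_id {l.gene_id!r}")
        seen.add(l.gene_id)

    by_chrom: dict[str, list[GeneLocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chromosome, []).append(l)

    clusters = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.gene_id))
        chain = [genes[0]]
        gaps: list[int] = []
        for prev, cur in zip(genes, genes[1:]):
            gap = gene_gap(prev, cur)
            if gap <= max_gap:
                chain.append(cur)
                gaps.append(gap)
            else:
                if len(chain) > 1:
                    clusters.append(
                        ClusterCall(tuple(g.gene_id for g in chain), chrom, tuple(gaps))
                    )
                chain = [cur]
                gaps = []
        if len(chain) > 1:
            clusters.append(
                ClusterCall(tuple(g.gene_id for g in chain), chrom, tuple(gaps))
            )
    return clusters


def chromosome_density(
    counts: dict[str, int],
    lengths_mb: dict[str, float],
    x_label: str = "X",
    decimals: int | None = 2,
) -> dict[str, float]:
    """Targets per Mb per chromosome, plus a pooled ``autosomes`` entry.

    ``decimals=2`` (the report default) rounds half-up; pass ``None`` for
    full precision.
    """
    missing = set(counts) - set(lengths_mb)
    if missing:
        raise ValueError(f"no length for chromosomes: {sorted(missing)}")
    if any(v <= 0 for v in lengths_mb.values()):
        raise ValueError("chromosome lengths must be positive")
    out = {}
    for chrom in counts:
        out[chrom] = counts[chrom] / lengths_mb[chrom]
    auto = [c for c in counts if c != x_label]
    if auto:
        out["autosomes"] = sum(counts[c] for c in auto) / sum(
            lengths_mb[c] for c in auto
        )
    if decimals is not None:
        out = {k: _round_half_up(v, decimals) for k, v in out.items()}
    return out


def chisq_distribution_test(
    observed: dict[str, int],
    lengths_mb: dict[str, float],
    expectation: str = "length_proportional",
    grouping: str = "per_chromosome",
    x_label: str = "X",
) -> ChiSquareResult:
    """Pearson goodness-of-fit of target counts across chromosome classes.

    ``expectation`` is ``length_proportional`` (expected counts follow
    chromosome length) or ``uniform``; ``grouping`` is ``per_chromosome`` or
    ``x_vs_autosomes`` (pool every non-X chromosome).
    """
    if expectation not in ("length_proportional", "uniform"):
        raise ValueError(f"unknown expectation model {expectation!r}")
    if grouping not in ("per_chromosome", "x_vs_autosomes"):
        raise ValueError(f"unknown grouping {grouping!r}")
    missing = set(observed) - set(lengths_mb)
    if missing:
        raise ValueError(f"no length for chromosomes: {sorted(missing)}")

    if grouping == "x_vs_autosomes":
        if x_label not in observed:
            raise ValueError(f"grouping requires chromosome {x_label!r}")
        obs = [
            observed[x_label],
            sum(v for k, v in observed.items() if k != x_label),
        ]
        lens = [
            lengths_mb[x_label],
            sum(lengths_mb[k] for k in observed if k != x_label),
        ]
    else:
        keys = sorted(observed)
        obs = [observed[k] for k in keys]
        lens = [lengths_mb[k] for k in keys]
    if len(obs) < 2:
        raise ValueError("need at least two classes")

    total = sum(obs)
    if expectation == "length_proportional":
        tot_len = sum(lens)
        exp = [total * l / tot_len for l in lens]
    else:
        exp = [total / len(obs)] * len(obs)
    if any(e <= 0 for e in exp):
        raise ValueError("degenerate expectation: an expected count is zero")

    stat, p = _sps.chisquare(obs, f_exp=exp)
    return ChiSquareResult(float(stat), len(obs) - 1, float(p))
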