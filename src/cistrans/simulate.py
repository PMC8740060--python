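"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream analysis
assumes, so the whole pipeline runs and is testable without any download:

* allele-origin read counts for two parental subspecies and their hybrid
  under known cis (c) and trans (t) regulatory effects — parental expression
  ratio E[P_pse/P_bog] = c*t, hybrid allelic ratio E[H_pse/H_bog] = c,
  because both hybrid alleles share one trans environment;
* gene loci on chromosomes of given lengths, with optional planted gene
  pairs at an exact inter-gene gap;
* two-subspecies alignment panels with planted fixed differences and
  within-subspecies polymorphisms;
* replicate count matrices for parents and hybrid under known inheritance
  modes (transgressive / additive / non-differential).

Counts follow the standard ASE simulation convention: a negative-binomial
class total (variance mu + dispersion * mu^2) split binomially between the
two allele origins.  Randomness is hierarchical — one global seed spawns an
independent stream per gene — so per-gene draws are stable under reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import GeneLocus
from .panel import AlignmentPanel

__all__ = [
    "CATEGORIES",
    "GENERATIVE_CATEGORIES",
    "INHERITANCE_MODES",
    "SimulationConfig",
    "SimulatedTruth",
    "benchmark_config",
    "simulate_regulatory_counts",
    "simulate_gene_annotation",
    "simulate_alignment_panel",
    "simulate_inheritance_counts",
]

#: The six regulatory-divergence categories assigned by the classifier.
CATEGORIES = (
    "conserved",
    "cis_only",
    "trans_only",
    "cis_and_trans",
    "compensatory",
    "ambiguous",
)

#: Categories with a generative model.  "ambiguous" is the classifier's
#: residual for test-outcome patterns that no regulatory scenario produces
#: deterministically, so it cannot be planted.
GENERATIVE_CATEGORIES = CATEGORIES[:5]

INHERITANCE_MODES = (
    "transgressive_up",
    "transgressive_down",
    "additive",
    "non_differential",
)

_NUC = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of the regulatory-count generator.

    Attributes
    ----------
    n_genes : number of genes to simulate.
    category_proportions : fraction of genes per regulatory category; must
        sum to 1.  "ambiguous" may appear only with fraction 0.
    cis_fold_range, trans_fold_range : interval of fold effects (>= 1) from
        which |effects| are drawn log-uniformly; the direction of each
        effect (above vs below 1) is a fair coin per gene.
    base_mean_range : interval for the per-gene baseline mean mu, the
        expected read total of one allele class in one replicate.
    dispersion : negative-binomial overdispersion alpha (variance
        mu + alpha * mu^2).
    n_replicates : replicate libraries per sample class.
    library_depth_factors : per-replicate depth multipliers (shared across
        the four classes); defaults to all 1.
    hybrid_factor : common scaling of both hybrid allele classes relative
        to the parents (the shared trans environment scales the alleles
        together, never apart).
    seed : global seed for the hierarchical per-gene streams.
    """

    n_genes: int
    category_proportions: dict[str, float]
    cis_fold_range: tuple[float, float] = (2.0, 8.0)
    trans_fold_range: tuple[float, float] = (2.0, 8.0)
    base_mean_range: tuple[float, float] = (100.0, 1000.0)
    dispersion: float = 0.05
    n_replicates: int = 3
    library_depth_factors: tuple[float, ...] | None = None
    hybrid_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be non-negative")
        unknown = set(self.category_proportions) - set(CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories: {sorted(unknown)}")
        if abs(sum(self.category_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("category_proportions must sum to 1")
        if any(v < 0 for v in self.category_proportions.values()):
            raise ConfigurationError("category proportions must be >= 0")
        if self.category_proportions.get("ambiguous", 0.0) > 0:
            raise ConfigurationError(
                "'ambiguous' has no generative model and cannot be planted"
            )
        for name in ("cis_fold_range", "trans_fold_range", "base_mean_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must satisfy 0 < lower <= upper")
        for name in ("cis_fold_range", "trans_fold_range"):
            if getattr(self, name)[0] < 1.0:
                raise ConfigurationError(f"{name} lower bound must be >= 1 (fold)")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.hybrid_factor <= 0:
            raise ConfigurationError("hybrid_factor must be positive")
        if self.library_depth_factors is None:
            self.library_depth_factors = tuple([1.0] * self.n_replicates)
        self.library_depth_factors = tuple(float(f) for f in self.library_depth_factors)
        if len(self.library_depth_factors) != self.n_replicates:
            raise ConfigurationError(
                "library_depth_factors must have one entry per replicate"
            )
        if any(f <= 0 for f in self.library_depth_factors):
            raise ConfigurationError("library depth factors must be positive")


@dataclass(frozen=True)
class SimulatedTruth:
    """Planted per-gene ground truth: category and the (c, t) effects."""

    gene_id: str
    true_category: str
    c: float
    t: float


def benchmark_config(seed: int = 42) -> SimulationConfig:
    """The packaged classifier benchmark.

    600 genes split evenly over the five generative categories, |log2 c| and
    |log2 t| equal to 2 wherever an effect is present, baseline mean 500
    reads per allele class, three replicates.
    """
    return SimulationConfig(
        n_genes=600,
        category_proportions={k: 0.2 for k in GENERATIVE_CATEGORIES},
        cis_fold_range=(4.0, 4.0),
        trans_fold_range=(4.0, 4.0),
        base_mean_range=(500.0, 500.0),
        dispersion=0.05,
        n_replicates=3,
        seed=seed,
    )


def _allocate(n: int, proportions: dict[str, float]) -> list[str]:
    """Deterministic largest-remainder allocation of genes to categories."""
    cats = [c for c in CATEGORIES if proportions.get(c, 0.0) > 0]
    raw = {c: n * proportions[c] for c in cats}
    counts = {c: int(math.floor(raw[c])) for c in cats}
    short = n - sum(counts.values())
    for c in sorted(cats, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    out = []
    for c in cats:
        out.extend([c] * counts[c])
    return out


def _nb_draw(rng: np.random.Generator, mean: float, alpha: float) -> int:
    """Negative-binomial draw with variance mean + alpha * mean^2."""
    size = 1.0 / alpha
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def _draw_fold(rng: np.random.Generator, lo: float, hi: float) -> float:
    """Log-uniform fold in [lo, hi], direction (>1 vs <1) by fair coin."""
    mag = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    return mag if rng.random() < 0.5 else 1.0 / mag


def simulate_regulatory_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, list[SimulatedTruth]]:
    """Generate per-gene allele-origin read totals under planted (c, t).

    Returns
    -------
    counts : DataFrame with columns gene_id, P_pse, P_bog, H_pse, H_bog,
        raw_total (raw parental read sum), summed across replicates.
    truth : list of :class:`SimulatedTruth`, one per gene.
    """
    categories = _allocate(config.n_genes, config.category_proportions)
    rows = []
    truth = []
    for i, cat in enumerate(categories):
        rng = np.random.default_rng([config.seed, i])
        c = t = 1.0
        if cat == "cis_only":
            c = _draw_fold(rng, *config.cis_fold_range)
        elif cat == "trans_only":
            t = _draw_fold(rng, *config.trans_fold_range)
        elif cat == "cis_and_trans":
            c = _draw_fold(rng, *config.cis_fold_range)
            t = _draw_fold(rng, *config.trans_fold_range)
            if math.isclose(t, 1.0 / c):  # that would be compensatory
                t = 1.0 / t
        elif cat == "compensatory":
            c = _draw_fold(rng, *config.cis_fold_range)
            t = 1.0 / c
        mu = rng.uniform(*config.base_mean_range)

        p_pse = p_bog = h_pse = h_bog = 0
        frac_parent = (c * t) / (1.0 + c * t)
        frac_hybrid = c / (1.0 + c)
        for f in config.library_depth_factors:
            tot_p = _nb_draw(rng, f * mu * (1.0 + c * t), config.dispersion)
            x = int(rng.binomial(tot_p, frac_parent)) if tot_p else 0
            p_pse += x
            p_bog += tot_p - x
            mean_h = f * mu * config.hybrid_factor * (1.0 + c)
            tot_h = _nb_draw(rng, mean_h, config.dispersion)
            y = int(rng.binomial(tot_h, frac_hybrid)) if tot_h else 0
            h_pse += y
            h_bog += tot_h - y

        gene = f"gene_{i:05d}"
        rows.append((gene, p_pse, p_bog, h_pse, h_bog, p_pse + p_bog))
        truth.append(SimulatedTruth(gene, cat, c, t))

    counts = pd.DataFrame(
        rows, columns=["gene_id", "P_pse", "P_bog", "H_pse", "H_bog", "raw_total"]
    )
    return counts, truth


def simulate_gene_annotation(
    n_genes: int,
    chromosome_lengths: dict[str, int],
    planted_clusters: list[tuple[str, int]] = (),
    seed: int = 0,
    gene_length_range: tuple[int, int] = (500, 3000),
    gap_range: tuple[int, int] = (20_000, 60_000),
) -> list[GeneLocus]:
    """Place non-overlapping gene loci on chromosomes.

    Background genes are laid down sequentially with inter-gene gaps drawn
    from ``gap_range`` (well above any clustering threshold of interest), so
    each entry of ``planted_clusters`` — a (chromosome, gap_bp) pair — yields
    the only adjacent gene pair whose closest-edge gap equals the requested
    value exactly.  Planted pair genes are additional to ``n_genes``.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    if any(l <= 0 for l in chromosome_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    for chrom, gap in planted_clusters:
        if chrom not in chromosome_lengths:
            raise ValueError(f"planted cluster on unknown chromosome {chrom!r}")
        if gap < 0:
            raise ValueError("planted gaps must be >= 0")
    if n_genes == 0 and not planted_clusters:
        return []

    rng = np.random.default_rng([seed, 2**20])
    chroms = sorted(chromosome_lengths)
    total_len = sum(chromosome_lengths.values())
    # length-proportional background allocation, largest remainder
    raw = {c: n_genes * chromosome_lengths[c] / total_len for c in chroms}
    alloc = {c: int(math.floor(raw[c])) for c in chroms}
    for c in sorted(chroms, key=lambda c: (-(raw[c] - alloc[c]), c))[
        : n_genes - sum(alloc.values())
    ]:
        alloc[c] += 1

    loci: list[GeneLocus] = []
    idx = 0
    for chrom in chroms:
        cursor = 1
        # planted pairs first, then background genes
        for k, (pc, gap) in enumerate(planted_clusters):
            if pc != chrom:
                continue
            for half in ("a", "b"):
                glen = int(rng.integers(*gene_length_range))
                start = cursor
                end = start + glen - 1
                if end > chromosome_lengths[chrom]:
                    raise ValueError(f"chromosome {chrom} too short for requested loci")
                loci.append(
                    GeneLocus(f"clu{k}_{half}", chrom, start, end, "+")
                )
                # next start at end + g gives a closest-edge gap of exactly g
                # (a planted gap of 0 means a 1 bp overlap)
                cursor = end + (gap if half == "a" else int(rng.integers(*gap_range)))
        for _ in range(alloc[chrom]):
            glen = int(rng.integers(*gene_length_range))
            start = cursor
            end = start + glen - 1
            if end > chromosome_lengths[chrom]:
                raise ValueError(f"chromosome {chrom} too short for requested loci")
            strand = "+" if rng.random() < 0.5 else "-"
            loci.append(GeneLocus(f"gene_{idx:05d}", chrom, start, end, strand))
            idx += 1
            cursor = end + int(rng.integers(*gap_range))
    return loci


def simulate_alignment_panel(
    n_strains_a: int,
    n_strains_b: int,
    length: int,
    n_fixed: int,
    n_poly_a: int = 0,
    n_poly_b: int = 0,
    alphabet: str = "nucleotide",
    seed: int = 0,
) -> tuple[AlignmentPanel, dict[str, list[int]]]:
    """Two-subspecies panel with planted fixed and polymorphic columns.

    Returns the panel and a truth dict with 1-based planted positions under
    keys ``fixed``, ``poly_pse`` and ``poly_bog``.  Fixed columns carry
    disjoint single residues in the two subspecies; polymorphic columns
    segregate within one subspecies only (which requires >=2 strains there).
    """
    if n_strains_a < 1 or n_strains_b < 1:
        raise ValueError("need at least one strain per subspecies")
    letters = _NUC if alphabet == "nucleotide" else _AA
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    n_sites = n_fixed + n_poly_a + n_poly_b
    if n_sites > length:
        raise ValueError("site budget exceeds alignment length")
    if n_poly_a and n_strains_a < 2:
        raise ValueError("polymorphism in pse requires >=2 pse strains")
    if n_poly_b and n_strains_b < 2:
        raise ValueError("polymorphism in bog requires >=2 bog strains")

    rng = np.random.default_rng([seed, 2**21])
    base = rng.choice(list(letters), size=length)
    cols = {s: base.copy() for s in range(n_strains_a + n_strains_b)}
    pse_idx = list(range(n_strains_a))
    bog_idx = list(range(n_strains_a, n_strains_a + n_strains_b))

    positions = rng.choice(length, size=n_sites, replace=False) + 1
    fixed = sorted(int(p) for p in positions[:n_fixed])
    poly_a = sorted(int(p) for p in positions[n_fixed : n_fixed + n_poly_a])
    poly_b = sorted(int(p) for p in positions[n_fixed + n_poly_a :])

    def _alt(ch: str) -> str:
        choices = [l for l in letters if l != ch]
        return str(rng.choice(choices))

    for pos in fixed:
        alt = _alt(str(base[pos - 1]))
        for s in bog_idx:
            cols[s][pos - 1] = alt
    for pos, idx_set in [(p, pse_idx) for p in poly_a] + [
        (p, bog_idx) for p in poly_b
    ]:
        alt = _alt(str(base[pos - 1]))
        k = int(rng.integers(1, len(idx_set)))  # proper non-empty subset
        carriers = rng.choice(idx_set, size=k, replace=False)
        for s in carriers:
            cols[s][pos - 1] = alt

    sequences = {}
    subspecies = {}
    for j, s in enumerate(pse_idx):
        name = f"pse_{j:02d}"
        sequences[name] = "".join(cols[s])
        subspecies[name] = "pse"
    for j, s in enumerate(bog_idx):
        name = f"bog_{j:02d}"
        sequences[name] = "".join(cols[s])
        subspecies[name] = "bog"
    panel = AlignmentPanel(sequences, subspecies, alphabet)
    return panel, {"fixed": fixed, "poly_pse": poly_a, "poly_bog": poly_b}


def simulate_inheritance_counts(
    n_genes: int,
    mode_proportions: dict[str, float],
    fold: float = 4.0,
    depth: float = 500.0,
    dispersion: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Replicate count matrices for the two parents and the hybrid.

    Per mode: ``non_differential`` genes have all three means equal to
    ``depth``; ``additive`` genes have parents at depth and depth*fold with
    the hybrid at their midpoint; ``transgressive_up``/``down`` genes have
    both parents at depth and the hybrid at depth*fold / depth/fold.

    Returns (parent_pse, parent_bog, hybrid) count DataFrames (genes x
    replicates) and the list of true modes.
    """
    unknown = set(mode_proportions) - set(INHERITANCE_MODES)
    if unknown:
        raise ConfigurationError(f"unknown inheritance modes: {sorted(unknown)}")
    if abs(sum(mode_proportions.values()) - 1.0) > 1e-9:
        raise ConfigurationError("mode_proportions must sum to 1")
    if fold <= 0 or depth <= 0 or dispersion <= 0:
        raise ConfigurationError("fold, depth and dispersion must be positive")

    order = [m for m in INHERITANCE_MODES if mode_proportions.get(m, 0) > 0]
    raw = {m: n_genes * mode_proportions[m] for m in order}
    counts = {m: int(math.floor(raw[m])) for m in order}
    for m in sorted(order, key=lambda m: (-(raw[m] - counts[m]), m))[
        : n_genes - sum(counts.values())
    ]:
        counts[m] += 1
    modes = []
    for m in order:
        modes.extend([m] * counts[m])

    mats = {k: np.zeros((n_genes, n_replicates), dtype=int) for k in "abh"}
    for i, mode in enumerate(modes):
        rng = np.random.default_rng([seed, 2**22 + i])
        if mode == "non_differential":
            ma = mb = mh = depth
        elif mode == "additive":
            ma, mb = depth, depth * fold
            mh = (ma + mb) / 2.0
        elif mode == "transgressive_up":
            ma = mb = depth
            mh = depth * fold
        else:  # transgressive_down
            ma = mb = depth
            mh = depth / fold
        for j in range(n_replicates):
            mats["a"][i, j] = _nb_draw(rng, ma, dispersion)
            mats["b"][i, j] = _nb_draw(rng, mb, dispersion)
            mats["h"][i, j] = _nb_draw(rng, mh, dispersion)

    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    cols = [f"rep{j + 1}" for j in range(n_replicates)]
    make = lambda k: pd.DataFrame(mats[k], index=genes, columns=cols)
    return make("a"), make("b"), make("h"), modes
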