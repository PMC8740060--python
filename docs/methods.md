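# Methods

## The ASE model and its assumptions

The pipeline classifies regulatory divergence between two subspecies from
four per-gene read classes: parental expression at fixed diagnostic SNPs
(`P_pse`, `P_bog`) and hybrid allelic expression (`H_pse`, `H_bog`). The
identifying assumption is the standard one for F1 ASE designs: cis-regulatory
variants act allele-specifically, while both alleles inside a hybrid share a
single trans-acting environment. Writing *c* for the cis fold effect and *t*
for the trans fold effect, the parental ratio has expectation *c·t* and the
hybrid allelic ratio has expectation *c*. The three exact tests (two binomial,
one Fisher 2×2) probe *c·t* ≠ 1, *c* ≠ 1 and *t* ≠ 1 respectively, and the
6-category map over the three significance flags follows from that algebra.
Three of the eight flag patterns (e.g. parental divergence with neither
hybrid imbalance nor a ratio shift) have no deterministic regulatory
interpretation — they arise from power failures — and form the "ambiguous"
residual.

Assumptions worth keeping in mind: reads at fixed SNPs are unbiased between
alleles (no mapping bias), SNP counts within a gene are exchangeable (they
are summed), and replicates are summed per class before testing because the
exact tests operate on single count pairs. Per-replicate testing would be a
sensitivity analysis, not the default.

## Tests and numerical conventions

* **Binomial exact test** — two-sided by the minimum-likelihood rule (sum of
  all outcome probabilities not exceeding the observed one), null proportion
  0.5. After depth adjustment across the four classes, 0.5 is the only
  coherent null.
* **Fisher 2×2 and Freeman–Halton 2×3** — direct enumeration of all tables
  with the observed margins, including every table whose probability is at
  most the observed table's (with a 1 + 1e-7 relative slack so exact ties
  survive floating point, the same convention as R's `fisher.test`).
  Probabilities come from `hypergeom.logpmf` (2×2) or log-gamma margin
  factorials (r×c). Enumeration is exact, so the r×c test caps the table
  total at 200 and rejects larger inputs rather than approximating.
* **FDR** — Benjamini–Hochberg step-up, applied separately within each of
  the three test families across genes. The default significance threshold
  is q < 0.005 (0.5%); `alpha` is exposed everywhere since 5% is the more
  common convention.
* **Rounding** — depth-adjusted counts can be non-integer; they are rounded
  half-up before the exact tests. Report densities are rounded half-up to
  two decimals; full precision is kept internally.

## Filters and depth adjustment

A SNP is diagnostic when each parent shows exactly one allele (tri-allelic
or within-parent polymorphic sites are rejected), the alleles differ, and
each allele has ≥ 3 supporting reads summed over that subspecies' samples.
Genes need ≥ 20 summed parental reads (`P_pse + P_bog`) to be retained.
Depth adjustment rescales each class by (smallest class library total / its
class library total) and then floors zeros to 1 so every test is defined.
The class totals are **library-level inputs**, not sums over the analysed
gene set: in a targeted gene panel most genes carry real signal, so realized
per-class sums would be contaminated by the very effects under test. The
synthetic pipeline therefore passes equal class totals (its libraries share
one simulated depth), making the adjustment the identity plus the zero
floor.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the packaged benchmark.

* **Counts** — per gene, a negative-binomial class total (variance
  μ + αμ², α = 0.05 by default — a typical biological-replicate
  overdispersion) split binomially between origins with probability
  *c·t*/(1 + *c·t*) (parents) or *c*/(1 + *c*) (hybrid). Marginal means are
  μ·*c·t* and μ for the parents; the hybrid shares a common scaling of both
  alleles. Effects are drawn log-uniformly from the configured fold range
  with a fair-coin direction; compensatory genes set *t* = 1/*c* exactly.
  Replicates (3 by default) are drawn independently and summed downstream.
* **Ambiguous is not plantable** — no (c, t) produces the residual patterns
  deterministically, so the configuration rejects a nonzero ambiguous
  proportion and the benchmark uses the five generative categories at
  120 genes each (600 total, |log2 effect| = 2, μ = 500, seed 42).
* **Loci** — background genes are placed sequentially with inter-gene gaps
  drawn from 20–60 kb, far above the 5.5 kb clustering threshold, so planted
  pairs with an exact requested gap are the only sub-threshold neighbours.
* **Panels** — a shared random background sequence; fixed columns flip all
  `bog` strains to a different residue; polymorphic columns give a proper
  non-empty strain subset of one subspecies an alternative residue.
* **Inheritance counts** — non-differential genes put all three groups at
  `depth`; additive genes separate the parents by `fold` with the hybrid at
  the midpoint; transgressive genes put the hybrid at `fold` above (or
  below) both parents.
* **Randomness** — one global seed spawns an independent
  `numpy.random.Generator` per gene (`default_rng([seed, index])`), so
  per-gene draws are stable under reordering and reruns are byte-identical.

What the generator does *not* emulate: mapping bias, SNP-level count
correlation within genes, library-composition effects, linkage among genes,
or the read-level error process. Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that real-data
confounders are handled.

## Sequence screens

Alignment columns are the coordinate system; columns containing an
alignment gap in any strain are skipped entirely (the conservative choice)
and ambiguity codes (N for nucleotide, X for protein, ?) are missing data,
never alleles. A column is a fixed difference when each subspecies carries
exactly one residue among non-missing strains and the residues differ; it
is polymorphic within a subspecies when ≥ 2 residues segregate there (the
two calls are mutually exclusive by construction). Upstream windows anchor
at the TSS with no position 0 (−1 abuts +1), inclusive ends, and a default
ladder of −500/−1000/−2000/−3000 each to +200; counts are monotone over the
nested ladder. Minus-strand genes are expected to be supplied already
reverse-complemented so "upstream" is 5′ of the transcript.

Diagnostic-haplotype separation asks whether any joint residue pattern over
the variable columns is shared across the subspecies boundary; strains with
missing data at a queried column are excluded from the comparison. The
distinguishing column set is greedy (leftmost-first growth, then a prune
pass) — it always separates when separation exists but is not guaranteed
minimal, since exhaustive minimisation is exponential and unnecessary for
the biological claim. Protein substitution positions use the ungapped
numbering of the first `pse` strain, matching the single-protein coordinate
convention of substitution labels like R24K.

## Distribution statistics

Inter-gene distance is the closest-edge gap, `later.start − earlier.end`,
clipped at 0 for overlaps — the convention recovered from the printed
cluster-pair coordinates. The cluster threshold defaults to 5500 bp: the
"approximately 5 kb" reading that keeps a printed 5202 bp pair together
where a strict 5000 would drop it; it is configurable. The chi-square
goodness-of-fit supports length-proportional and uniform expectations and
per-chromosome or X-vs-autosomes grouping; the published per-chromosome
statistics could not be reconstructed from the printed counts under either
expectation model, so only the operation's arithmetic is verified, against
a hand-rolled Σ(O−E)²/E.

## Problem sizes and known limitations

The packaged benchmark (600 genes), the null run (1000 genes), and the
oracle enumerations (exhaustive at small table totals, seeded sampling up
to total 60) are sized so the full suite and the acceptance script each run
in well under a minute on one core while keeping every estimate's Monte
Carlo error far from its acceptance margin. The DE caller used for
inheritance modes is deliberately a stand-in (Welch's t on log2(count+1));
production analyses should supply external DE calls (e.g. a DESeq2 + edgeR
consensus at FDR 5%, |lfc| > 1) in the documented schema. The Freeman–Halton
cap (2×3, total ≤ 200) suits target-panel group comparisons, not
genome-scale tables.
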