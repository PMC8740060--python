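"""Protein-panel screens for candidate trans-regulatory factors.

Candidate factors (DNA/RNA-binding proteins within hybrid-male-sterility
loci) are screened on multi-strain protein alignment panels for fixed
amino-acid substitutions between the subspecies, for subspecies-diagnostic
haplotypes (joint patterns over variable residues that separate the
subspecies even without any single fixed residue), and for substitutions
falling inside annotated binding domains.  Substitution positions follow
the ungapped numbering of the reference sequence, the first ``pse`` strain
of the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .panel import AlignmentPanel, GAP_CHARS, fixed_columns, haplotypes_separate, variable_columns

__all__ = [
    "DomainAnnotation",
    "SubstitutionRecord",
    "find_fixed_aa_substitutions",
    "diagnostic_haplotypes",
    "substitutions_in_domains",
]


@dataclass(frozen=True)
class DomainAnnotation:
    """A named domain interval, 1-based inclusive residue positions."""

    protein_id: str
    domain: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.protein_id}/{self.domain}: bad interval")


@dataclass(frozen=True)
class SubstitutionRecord:
    protein_id: str
    position: int  # ungapped pse-reference residue index
    residue_pse: str
    residue_bog: str
    in_domain: bool = False

    @property
    def label(self) -> str:
        """Conventional substitution label, e.g. ``R24K``."""
        return f"{self.residue_pse}{self.position}{self.residue_bog}"


def _reference_positions(panel: AlignmentPanel) -> tuple[str, list[int]]:
    """Ungapped residue index of every alignment column in the reference
    (first pse strain); 0 where the reference has a gap."""
    pse = panel.strains("pse")
    if not pse:
        raise ValueError("panel has no pse strains")
    ref_name = pse[0]
    seq = panel.sequences[ref_name]
    out = []
    pos = 0
    for ch in seq:
        if ch not in GAP_CHARS:
            pos += 1
            out.append(pos)
        else:
            out.append(0)
    return ref_name, out


def find_fixed_aa_substitutions(
    panel: AlignmentPanel, protein_id: str = "protein"
) -> list[SubstitutionRecord]:
    """Fixed amino-acid differences between the subspecies.

    Same fixed-column rule as the nucleotide screen (one residue per
    subspecies among non-missing strains, residues differ, gapped columns
    skipped); positions reported in ungapped pse-reference numbering.
    """
    if panel.alphabet != "protein":
        raise ValueError("protein panel required")
    _, refpos = _reference_positions(panel)
    pse = panel.strains("pse")
    bog = panel.strains("bog")
    records = []
    for col in fixed_columns(panel):
        col_res = panel.column(col)
        res_pse = next(
            r for s in pse if (r := col_res[s]) not in "X?"
        )
        res_bog = next(r for s in bog if (r := col_res[s]) not in "X?")
        records.append(SubstitutionRecord(protein_id, refpos[col - 1], res_pse, res_bog))
    return records


def diagnostic_haplotypes(panel: AlignmentPanel) -> tuple[bool, tuple[int, ...]]:
    """Whether joint residue patterns separate the subspecies, and a small
    distinguishing column set.

    ``separating`` is True iff no full-length haplotype over all variable
    columns is shared between subspecies.  The distinguishing set is found
    greedily: columns are added leftmost-first until the set separates, then
    pruned left to right; it always separates when ``separating`` is True,
    but is not guaranteed to be globally minimal.
    """
    variable = variable_columns(panel)
    if not variable or not haplotypes_separate(panel, variable):
        return False, ()
    chosen: list[int] = []
    for col in variable:
        chosen.append(col)
        if haplotypes_separate(panel, chosen):
            break
    for col in list(chosen):
        trimmed = [c for c in chosen if c != col]
        if trimmed and haplotypes_separate(panel, trimmed):
            chosen = trimmed
    return True, tuple(chosen)


def substitutions_in_domains(
    subs: list[SubstitutionRecord],
    domains: list[DomainAnnotation],
    protein_length: int | None = None,
) -> tuple[list[SubstitutionRecord], dict[str, int]]:
    """Mark substitutions inside annotated domains (inclusive bounds).

    Returns the annotated records and a per-domain substitution tally.
    """
    if protein_length is not None:
        for s in subs:
            if s.position > protein_length:
                raise ValueError(
                    f"{s.protein_id}: position {s.position} beyond protein "
                    f"length {protein_length}"
                )
    counts = {d.domain: 0 for d in domains}
    out = []
    for s in subs:
        hit = False
        for d in domains:
            if d.protein_id == s.protein_id and d.start <= s.position <= d.end:
                counts[d.domain] += 1
                hit = True
        out.append(replace(s, in_domain=hit))
    return out, counts
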