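"""Two-subspecies alignment panels and fixed/polymorphic column calls.

An :class:`AlignmentPanel` holds an aligned set of sequences (nucleotide or
protein) for strains of the two Drosophila pseudoobscura subspecies,
``pse`` (D. p. pseudoobscura) and ``bog`` (D. p. bogotana).  A column is a
*fixed difference* when, among non-missing residues, each subspecies carries
exactly one residue and the two residues differ; it is *polymorphic* within a
subspecies when at least two residues segregate there.  Columns containing an
alignment gap in any strain are skipped for both calls, and ambiguity codes
(N for nucleotide, X for protein, ? for either) count as missing data rather
than alleles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "AlignmentPanel",
    "SUBSPECIES",
    "fixed_columns",
    "segregating_columns",
    "variable_columns",
    "haplotypes_separate",
]

SUBSPECIES = ("pse", "bog")
GAP_CHARS = frozenset("-.")
_MISSING = {"nucleotide": frozenset("N?"), "protein": frozenset("X?")}


@dataclass
class AlignmentPanel:
    """Aligned sequences keyed by strain, with a subspecies label per strain.

    Parameters
    ----------
    sequences : mapping strain -> aligned sequence (equal lengths).
    subspecies : mapping strain -> ``"pse"`` or ``"bog"``.
    alphabet : ``"nucleotide"`` or ``"protein"``; controls which ambiguity
        code is treated as missing data.
    """

    sequences: dict[str, str]
    subspecies: dict[str, str]
    alphabet: str = "nucleotide"

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("panel has no sequences")
        if set(self.sequences) != set(self.subspecies):
            raise ValueError("sequence and subspecies strain sets differ")
        if self.alphabet not in _MISSING:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal aligned sequence lengths: {sorted(lengths)}")
        bad = {v for v in self.subspecies.values()} - set(SUBSPECIES)
        if bad:
            raise ValueError(f"unknown subspecies labels: {sorted(bad)}")
        self.sequences = {k: v.upper() for k, v in self.sequences.items()}

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def strains(self, label: str | None = None) -> list[str]:
        if label is None:
            return list(self.sequences)
        return [s for s, sub in self.subspecies.items() if sub == label]

    def slice(self, start: int, end: int) -> "AlignmentPanel":
        """Sub-panel over 1-based inclusive column range [start, end]."""
        if not 1 <= start <= end <= self.length:
            raise ValueError(f"column range [{start}, {end}] outside 1..{self.length}")
        return AlignmentPanel(
            {k: v[start - 1 : end] for k, v in self.sequences.items()},
            dict(self.subspecies),
            self.alphabet,
        )

    def column(self, col: int) -> dict[str, str]:
        """Residue per strain at 1-based column ``col``."""
        return {k: v[col - 1] for k, v in self.sequences.items()}


def _column_state(panel: AlignmentPanel, col: int):
    """Per-subspecies residue sets at a column, or None if the column is gapped."""
    missing = _MISSING[panel.alphabet]
    out = {lab: set() for lab in SUBSPECIES}
    for strain, seq in panel.sequences.items():
        ch = seq[col - 1]
        if ch in GAP_CHARS:
            return None
        if ch in missing:
            continue
        out[panel.subspecies[strain]].add(ch)
    return out


def fixed_columns(panel: AlignmentPanel) -> list[int]:
    """1-based columns that are fixed differences between the subspecies."""
    _require_both(panel)
    out = []
    for col in range(1, panel.length + 1):
        state = _column_state(panel, col)
        if state is None:
            continue
        a, b = state["pse"], state["bog"]
        if len(a) == 1 and len(b) == 1 and a != b:
            out.append(col)
    return out


def segregating_columns(panel: AlignmentPanel, label: str) -> list[int]:
    """1-based columns polymorphic within one subspecies."""
    if label not in SUBSPECIES:
        raise ValueError(f"subspecies must be one of {SUBSPECIES}, got {label!r}")
    if len(panel.strains(label)) < 2:
        raise ValueError(f"need >=2 {label} strains to assess polymorphism")
    out = []
    for col in range(1, panel.length + 1):
        state = _column_state(panel, col)
        if state is not None and len(state[label]) >= 2:
            out.append(col)
    return out


def variable_columns(panel: AlignmentPanel) -> list[int]:
    """Ungapped columns with >=2 residues among all non-missing strains."""
    out = []
    for col in range(1, panel.length + 1):
        state = _column_state(panel, col)
        if state is not None and len(state["pse"] | state["bog"]) >= 2:
            out.append(col)
    return out


def haplotypes_separate(panel: AlignmentPanel, columns) -> bool:
    """True iff no joint residue pattern over ``columns`` is shared between
    subspecies.

    Strains with missing data at any queried column are excluded from the
    comparison; a subspecies with no fully observed strain cannot be shown to
    separate and yields False.
    """
    cols = list(columns)
    if not cols:
        return False
    missing = _MISSING[panel.alphabet] | GAP_CHARS
    pats = {lab: set() for lab in SUBSPECIES}
    for strain, seq in panel.sequences.items():
        pat = tuple(seq[c - 1] for c in cols)
        if any(ch in missing for ch in pat):
            continue
        pats[panel.subspecies[strain]].add(pat)
    if not pats["pse"] or not pats["bog"]:
        return False
    return not (pats["pse"] & pats["bog"])


def _require_both(panel: AlignmentPanel) -> None:
    for lab in SUBSPECIES:
        if not panel.strains(lab):
            raise ValueError(f"panel has no {lab} strains")
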