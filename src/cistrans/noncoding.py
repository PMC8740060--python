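"""Fixed-difference and polymorphism screens in TSS-anchored windows.

Windows are anchored on the transcription start site with the promoter axis
skipping position 0: ...-2, -1, +1, +2... with +1 the TSS column itself.  A
window (upstream u, downstream d) therefore spans u + d alignment columns.
Counts follow the panel column rules (gap columns skipped, N/X/? missing);
fixed-substitution counts are reported over a ladder of nested upstream
windows (-500, -1000, -2000, -3000, each to +200 by default), and motif
(e.g. Adf-1) site intervals are screened both for fixed columns and for
joint polymorphic patterns that separate the subspecies without any single
fixed site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .panel import (
    AlignmentPanel,
    fixed_columns,
    haplotypes_separate,
    segregating_columns,
    variable_columns,
)

__all__ = [
    "WindowSpec",
    "MotifSite",
    "extract_window",
    "count_fixed_differences",
    "count_polymorphisms",
    "motif_site_divergence",
    "window_ladder_counts",
]

DEFAULT_LADDER = (500, 1000, 2000, 3000)


@dataclass(frozen=True)
class WindowSpec:
    """A TSS-anchored window: ``upstream_extent`` bp before the TSS and
    ``downstream_extent`` bp from the TSS on (position +1 included)."""

    upstream_extent: int
    downstream_extent: int = 200

    def __post_init__(self):
        if self.upstream_extent < 0 or self.downstream_extent < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream_extent + self.downstream_extent == 0:
            raise ValueError("degenerate window of zero extent")


@dataclass(frozen=True)
class MotifSite:
    """A motif-site interval on the TSS axis, inclusive ends, no position 0."""

    gene_id: str
    start: int
    end: int

    def __post_init__(self):
        if self.start == 0 or self.end == 0:
            raise ValueError("the TSS axis has no position 0")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: site start > end")

    def positions(self):
        return [p for p in range(self.start, self.end + 1) if p != 0]


def axis_to_column(position: int, upstream_extent: int) -> int:
    """Map a TSS-axis position to a 1-based column of the window panel."""
    if position == 0:
        raise ValueError("the TSS axis has no position 0")
    return upstream_extent + position + (1 if position < 0 else 0)


def extract_window(
    panel: AlignmentPanel, tss_column: int, window: WindowSpec
) -> AlignmentPanel:
    """Sub-panel over the window; ``tss_column`` is the column of position +1.

    A window reaching past the alignment is truncated with a warning.
    """
    if not 1 <= tss_column <= panel.length:
        raise ValueError(f"tss_column {tss_column} outside alignment 1..{panel.length}")
    start = tss_column - window.upstream_extent
    end = tss_column + window.downstream_extent - 1
    if start < 1 or end > panel.length:
        warnings.warn(
            f"window [{start}, {end}] truncated to alignment 1..{panel.length}",
            stacklevel=2,
        )
        start, end = max(1, start), min(panel.length, end)
    return panel.slice(start, end)


def count_fixed_differences(panel: AlignmentPanel) -> tuple[int, list[int]]:
    """Number and 1-based positions of fixed inter-subspecies columns."""
    cols = fixed_columns(panel)
    return len(cols), cols


def count_polymorphisms(panel: AlignmentPanel, subspecies: str = "both") -> int:
    """Columns segregating within the queried subspecies (or within either)."""
    if subspecies == "both":
        pse = set(segregating_columns(panel, "pse"))
        bog = set(segregating_columns(panel, "bog"))
        return len(pse | bog)
    return len(segregating_columns(panel, subspecies))


def motif_site_divergence(
    window_panel: AlignmentPanel,
    sites: list[MotifSite],
    upstream_extent: int,
) -> pd.DataFrame:
    """Per motif site: fixed-column count and diagnostic joint pattern.

    ``window_panel`` must span the full (-upstream_extent .. +downstream)
    window so the TSS-axis site coordinates can be mapped to its columns.
    ``diagnostic_polymorphism`` is True when the joint residue pattern over
    the site's variable columns (fixed columns included) is shared by no
    strain pair across the subspecies boundary — i.e. the site separates the
    subspecies even without any single fixed difference.
    """
    fixed = set(fixed_columns(window_panel))
    variable = variable_columns(window_panel)
    rows = []
    for site in sites:
        cols = [axis_to_column(p, upstream_extent) for p in site.positions()]
        if min(cols) < 1 or max(cols) > window_panel.length:
            raise ValueError(
                f"{site.gene_id}: site [{site.start}, {site.end}] outside window"
            )
        span = set(cols)
        n_fixed = len(span & fixed)
        site_variable = [c for c in variable if c in span]
        diagnostic = haplotypes_separate(window_panel, site_variable)
        rows.append((site.gene_id, site.start, site.end, n_fixed, diagnostic))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "start", "end", "fixed_count", "diagnostic_polymorphism"],
    )


def window_ladder_counts(
    panel: AlignmentPanel,
    tss_column: int,
    ladder=DEFAULT_LADDER,
    downstream_extent: int = 200,
) -> pd.DataFrame:
    """Fixed and polymorphic column counts per nested upstream window."""
    rows = []
    for upstream in ladder:
        sub = extract_window(panel, tss_column, WindowSpec(upstream, downstream_extent))
        n_fixed, _ = count_fixed_differences(sub)
        rows.append((upstream, downstream_extent, n_fixed, count_polymorphisms(sub)))
    return pd.DataFrame(
        rows, columns=["upstream", "downstream", "fixed_count", "polymorphic_count"]
    )
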