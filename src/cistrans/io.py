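"""Table and alignment I/O for every pipeline schema.

The interchange dialect is TSV (tab-delimited, header row, UTF-8, ``.`` for
missing).  Gene loci travel as BED-like files (0-based half-open on disk)
and are converted to 1-based inclusive coordinates in memory.  Alignment
panels are aligned FASTA with ``strain|subspecies`` headers.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .distribution import GeneLocus
from .panel import AlignmentPanel, SUBSPECIES

__all__ = [
    "read_table",
    "write_table",
    "read_loci_bed",
    "write_loci_bed",
    "read_panel_fasta",
    "write_panel_fasta",
    "read_chromosome_lengths",
    "read_class_totals",
]


def read_table(path, required=None, numeric=None) -> pd.DataFrame:
    """Read a TSV with a header row, validating columns and numeric fields."""
    df = pd.read_csv(path, sep="\t", na_values=["."])
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    for col in numeric or []:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            lines = ", ".join(str(i + 2) for i in bad.index[:5])  # +2: header + 1-base
            raise ValueError(f"{path}: non-numeric {col!r} at line(s) {lines}") from exc
    return df


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_loci_bed(path) -> list[GeneLocus]:
    """Read BED-like loci (chrom, start, end, gene_id, strand; 0-based
    half-open) into 1-based inclusive :class:`GeneLocus` records."""
    loci = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start0, end0, gene_id = parts[:4]
            strand = parts[4] if len(parts) > 4 and parts[4] in "+-" else "?"
            try:
                s0, e0 = int(start0), int(end0)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if s0 < 0 or e0 <= s0:
                raise ValueError(f"{path}:{lineno}: empty or negative interval")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            loci.append(GeneLocus(gene_id, chrom, s0 + 1, e0, strand))
    return loci


def write_loci_bed(loci, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for l in loci:
            strand = l.strand if l.strand in "+-" else "."
            fh.write(f"{l.chromosome}\t{l.start - 1}\t{l.end}\t{l.gene_id}\t{strand}\n")


def read_panel_fasta(path, alphabet: str = "nucleotide") -> AlignmentPanel:
    """Read an aligned FASTA panel with ``strain|subspecies`` headers."""
    sequences, subspecies = {}, {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"{path}: header {rec.id!r} is not 'strain|subspecies'")
        strain, label = rec.id.rsplit("|", 1)
        if label not in SUBSPECIES:
            raise ValueError(f"{path}: unknown subspecies {label!r} for {strain!r}")
        sequences[strain] = str(rec.seq)
        subspecies[strain] = label
    if not sequences:
        raise ValueError(f"{path}: empty FASTA")
    return AlignmentPanel(sequences, subspecies, alphabet)


def write_panel_fasta(panel: AlignmentPanel, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=f"{strain}|{panel.subspecies[strain]}", description="")
        for strain, seq in panel.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_chromosome_lengths(path) -> dict[str, float]:
    df = read_table(path, required=["chrom", "length_mb"], numeric=["length_mb"])
    return dict(zip(df["chrom"].astype(str), df["length_mb"].astype(float)))


def read_class_totals(path) -> dict[str, float]:
    df = read_table(path, required=["class", "total"], numeric=["total"])
    return dict(zip(df["class"].astype(str), df["total"].astype(float)))
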