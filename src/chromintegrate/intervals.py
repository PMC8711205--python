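"""Genomic interval algebra and coordinate conventions.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers ``end - start`` bases.  Every other module builds on
the types and operations defined here.

Strand conventions
------------------
The transcription start site (TSS) of a plus-strand gene is the first base of
the gene body (``body.start``); for a minus-strand gene it is the last base
(``body.end - 1``).  TSS-anchored windows are mirrored on the minus strand so
that "upstream" always means 5' of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).  ``start`` is
    0-based inclusive, ``end`` 0-based exclusive; the span must be non-empty.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene body with an identifier and a strand-aware TSS.

    The TSS is the first transcribed base: ``body.start`` on the plus strand,
    ``body.end - 1`` on the minus strand.
    """

    gene_id: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r} must be stranded (+/-)")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        if self.body.strand == "+":
            return self.body.start
        return self.body.end - 1


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def tss_window(g: GeneModel, up: int, down: int) -> GenomicInterval:
    """Strand-aware window around a gene's TSS, clipped at the origin.

    ``up`` bases extend 5' of the TSS and ``down`` bases 3' (the TSS base
    itself belongs to the downstream side).  On the plus strand the window is
    ``[tss - up, tss + down)``; on the minus strand it is mirrored to
    ``[tss - down + 1, tss + up + 1)``.
    """
    if up < 0 or down < 0:
        raise ValueError("up and down must be non-negative")
    if up + down == 0:
        raise ValueError("degenerate TSS window (up = down = 0)")
    if g.body.strand == "+":
        lo, hi = g.tss - up, g.tss + down
    else:
        lo, hi = g.tss - down + 1, g.tss + up + 1
    return GenomicInterval(g.body.chrom, max(0, lo), hi, g.body.strand)


def genebody_flank(g: GeneModel, flank: int) -> GenomicInterval:
    """Gene body extended by ``flank`` bp on both sides (strand-independent)."""
    if flank < 0:
        raise ValueError("flank must be non-negative")
    return GenomicInterval(
        g.body.chrom,
        max(0, g.body.start - flank),
        g.body.end + flank,
        g.body.strand,
    )


def any_overlap(
    query: GenomicInterval,
    targets: Iterable[GenomicInterval],
    min_bp: int,
) -> tuple[bool, list[GenomicInterval]]:
    """Whether any target shares at least ``min_bp`` bases with ``query``.

    Returns the flag plus the qualifying targets sorted by (chrom, start).
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    hits = [t for t in targets if overlap_length(query, t) >= min_bp]
    hits.sort(key=lambda t: (t.chrom, t.start, t.end))
    return bool(hits), hits


# ---------------------------------------------------------------------------
# I/O — BED, bedGraph and gene tables (tab-separated, 0-based half-open)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals; columns beyond the sixth are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    strands = df[5] if df.shape[1] >= 6 else pd.Series(["."] * len(df))
    return [
        GenomicInterval(str(c), int(s), int(e), str(st) if st in STRANDS else ".")
        for c, s, e, st in zip(df[0], df[1], df[2], strands)
    ]


def write_bed(path: str | Path, intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a 4-column bedGraph into a DataFrame (chrom, start, end, value)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df["end"].le(df["start"]).any():
        raise FormatError(f"{path}: bedGraph record with end <= start")
    return df


def write_bedgraph(path: str | Path, track: pd.DataFrame) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a gene table TSV: chrom, start, end, strand, gene_id.

    A single leading '#' header line is tolerated.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "strand", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    return [
        GeneModel(str(g), GenomicInterval(str(c), int(s), int(e), str(st)))
        for c, s, e, st, g in zip(
            df["chrom"], df["start"], df["end"], df["strand"], df["gene_id"]
        )
    ]


def write_gene_table(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tstrand\tgene_id\n")
        for g in genes:
            b = g.body
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.strand}\t{g.gene_id}\n")
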