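"""Peak-to-feature annotation and transposable-element overlap summaries.

Peaks are assigned to the gene whose flanked body (default 10 kb on either
side) they overlap the most, with promoter/genebody precedence decided by the
TSS window; differential regions are summarised per TE class as the
percentage of direction-matched peaks overlapping at least one element of
that class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .differential import DifferentialRegion
from .intervals import (
    GeneModel,
    GenomicInterval,
    genebody_flank,
    overlap_length,
    tss_window,
)
from .peakcalling import PeakSet

TE_CLASSES = ("LTR", "SINE", "LINE", "DNA")
FEATURES = ("promoter", "genebody", "intergenic")


@dataclass(frozen=True)
class TEAnnotation:
    """A RepeatMasker-style transposable-element interval with its class."""

    region: GenomicInterval
    te_class: str

    def __post_init__(self) -> None:
        if not self.te_class:
            raise ValueError("te_class must be non-empty")


@dataclass(frozen=True)
class FeatureAssignment:
    """A peak's gene assignment and feature category."""

    peak: GenomicInterval
    gene_id: str | None
    feature: str

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if (self.gene_id is None) != (self.feature == "intergenic"):
            raise ValueError("gene_id is None exactly for intergenic peaks")


def assign_genes(
    peaks: PeakSet,
    genes: Sequence[GeneModel],
    flank: int = 10000,
    promoter_up: int = 5000,
    promoter_down: int = 3000,
) -> list[FeatureAssignment]:
    """Assign each peak to a gene within ``flank`` bp of its body.

    A peak overlapping several flanked gene bodies goes to the gene with the
    largest overlap (ties: smallest gene start, then gene_id).  Assigned
    peaks are ``promoter`` if they touch the TSS window, else ``genebody``;
    peaks hitting no flanked body are ``intergenic``.
    """
    flanked = [(g, genebody_flank(g, flank)) for g in genes]
    out: list[FeatureAssignment] = []
    for p in peaks.regions():
        best: GeneModel | None = None
        best_key: tuple[int, int, str] | None = None
        for g, fb in flanked:
            ov = overlap_length(p, fb)
            if ov > 0:
                key = (-ov, g.body.start, g.gene_id)
                if best_key is None or key < best_key:
                    best, best_key = g, key
        if best is None:
            out.append(FeatureAssignment(p, None, "intergenic"))
        elif overlap_length(p, tss_window(best, promoter_up, promoter_down)) > 0:
            out.append(FeatureAssignment(p, best.gene_id, "promoter"))
        else:
            out.append(FeatureAssignment(p, best.gene_id, "genebody"))
    return out


def feature_fractions(
    assignments: Sequence[FeatureAssignment],
) -> dict[str, float]:
    """Proportion of peaks per feature category; proportions sum to 1."""
    if not assignments:
        raise ValueError("feature_fractions needs at least one assignment")
    n = len(assignments)
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.feature] = counts.get(a.feature, 0) + 1
    return {feat: c / n for feat, c in sorted(counts.items())}


def te_overlap_proportions(
    diff: Sequence[DifferentialRegion],
    tes: Sequence[TEAnnotation],
    denominator: str = "te-overlapped",
) -> dict[tuple[str, str], float]:
    """Percent of differential peaks per (direction, TE class).

    For each direction the numerator is the number of peaks overlapping at
    least one TE of the class (a peak spanning several classes counts once
    per class).  The denominator is, by default, the number of
    TE-overlapped peaks of that direction; ``denominator="all"`` uses every
    peak of the direction instead.  Directions with a zero denominator are
    absent from the result.
    """
    if denominator not in ("te-overlapped", "all"):
        raise ValueError("denominator must be 'te-overlapped' or 'all'")
    for d in diff:
        if d.direction not in ("gained-open", "gained-closed"):
            raise ValueError(
                "te_overlap_proportions expects only directional peaks"
            )
    out: dict[tuple[str, str], float] = {}
    for direction in ("gained-open", "gained-closed"):
        peaks = [d.region for d in diff if d.direction == direction]
        per_peak_classes = [
            {
                t.te_class
                for t in tes
                if overlap_length(p, t.region) > 0
            }
            for p in peaks
        ]
        n_te = sum(1 for cls in per_peak_classes if cls)
        denom = len(peaks) if denominator == "all" else n_te
        if denom == 0:
            continue
        classes = sorted({c for cls in per_peak_classes for c in cls})
        for c in classes:
            hits = sum(1 for cls in per_peak_classes if c in cls)
            out[(direction, c)] = 100.0 * hits / denom
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_te_table(path: str | Path) -> list[TEAnnotation]:
    """TE table TSV: chrom, start, end, te_class."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "te_class"],
        dtype={"chrom": str, "te_class": str},
    )
    return [
        TEAnnotation(
            GenomicInterval(str(c), int(s), int(e)), str(k)
        )
        for c, s, e, k in zip(df["chrom"], df["start"], df["end"], df["te_class"])
    ]


def write_te_table(path: str | Path, tes: Sequence[TEAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tte_class\n")
        for t in tes:
            r = t.region
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{t.te_class}\n")


def write_assignments(
    path: str | Path, assignments: Sequence[FeatureAssignment]
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tfeature\n")
        for a in assignments:
            gid = a.gene_id if a.gene_id is not None else "."
            fh.write(
                f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t{gid}\t{a.feature}\n"
            )


def write_te_proportions(
    path: str | Path, props: Mapping[tuple[str, str], float]
) -> None:
    with open(path, "w") as fh:
        fh.write("#direction\tte_class\tpercent\n")
        for (direction, cls), pct in sorted(props.items()):
            fh.write(f"{direction}\t{cls}\t{pct:.6g}\n")
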