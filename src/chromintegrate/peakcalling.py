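"""Sparse-enrichment peak calling for CUT&RUN coverage tracks.

The caller follows the SEACR idea: contiguous runs of strictly positive
bedGraph signal are candidate peaks ("signal blocks"), scored by their total
signal (AUC = sum of value x segment length).  In stringent mode the top
``threshold`` fraction of blocks by AUC is retained.  On top of that sit the
post-processing steps used for H3K56ac profiling of VPA-treated mESCs:

* a half-mean filter that drops peaks whose AUC falls below half the mean
  AUC of the file;
* a replicate-consensus step that keeps regions reproduced in both
  replicates with at least ``min_overlap`` (default 300) shared bases;
* a condition-uniqueness step that keeps consensus peaks with zero overlap
  against the other condition's consensus set.

Only the numeric-threshold, stringent configuration is implemented; the
control-track (IgG) branch of SEACR is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import FormatError, GenomicInterval, overlap_length


@dataclass(frozen=True)
class SignalBlock:
    """A maximal run of positive coverage with its total and peak signal."""

    region: GenomicInterval
    auc: float
    max_value: float

    def __post_init__(self) -> None:
        if self.auc <= 0 or self.max_value <= 0:
            raise ValueError("signal block must carry positive signal")


@dataclass
class PeakSet:
    """Peaks for one condition/replicate, coordinate-sorted, non-overlapping."""

    condition: str
    replicate: str
    peaks: list[SignalBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda b: (b.region.chrom, b.region.start)
        )
        for a, b in zip(self.peaks, self.peaks[1:]):
            if overlap_length(a.region, b.region) > 0:
                raise ValueError("peaks within a PeakSet must not overlap")

    def __len__(self) -> int:
        return len(self.peaks)

    def regions(self) -> list[GenomicInterval]:
        return [p.region for p in self.peaks]


@dataclass(frozen=True)
class FragmentFilterSpec:
    """Paired-end fragment retention rule (fragments shorter than the cap)."""

    max_fragment_length: int = 1000
    same_chrom_required: bool = True

    def __post_init__(self) -> None:
        if self.max_fragment_length <= 0:
            raise ValueError("max_fragment_length must be positive")


def filter_fragments(
    fragments: Sequence[GenomicInterval],
    spec: FragmentFilterSpec = FragmentFilterSpec(),
) -> list[GenomicInterval]:
    """Keep fragments with length strictly below the cap, preserving order."""
    return [f for f in fragments if f.length < spec.max_fragment_length]


def segment_signal_blocks(track: pd.DataFrame) -> list[SignalBlock]:
    """Segment a bedGraph track into maximal runs of positive signal.

    ``track`` must hold columns chrom/start/end/value, sorted by
    (chrom, start) with chromosomes contiguous and records non-overlapping.
    Adjacent positive records that abut exactly merge into one block;
    zero-value records and coverage gaps separate blocks.
    """
    for col in ("chrom", "start", "end", "value"):
        if col not in track.columns:
            raise FormatError(f"bedGraph track missing column {col!r}")
    if len(track) == 0:
        return []

    chrom = track["chrom"].to_numpy()
    start = track["start"].to_numpy()
    end = track["end"].to_numpy()
    value = track["value"].to_numpy(dtype=float)

    same_chrom = chrom[1:] == chrom[:-1]
    if np.any(same_chrom & (start[1:] < end[:-1])):
        raise FormatError("bedGraph records unsorted or overlapping")
    n_segments = 1 + int(np.count_nonzero(~same_chrom)) if len(chrom) else 0
    if n_segments != len(np.unique(chrom)):
        raise FormatError("bedGraph chromosomes must be contiguous")

    pos = value > 0
    if not pos.any():
        return []
    c, s, e, v = chrom[pos], start[pos], end[pos], value[pos]
    # new block at a chromosome change or any gap between positive records
    brk = np.ones(len(c), dtype=bool)
    brk[1:] = (c[1:] != c[:-1]) | (s[1:] != e[:-1])
    block_id = np.cumsum(brk) - 1
    area = v * (e - s)

    df = pd.DataFrame(
        {"bid": block_id, "chrom": c, "start": s, "end": e, "area": area, "v": v}
    )
    agg = df.groupby("bid", sort=True).agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        auc=("area", "sum"),
        max_value=("v", "max"),
    )
    return [
        SignalBlock(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            float(r.auc),
            float(r.max_value),
        )
        for r in agg.itertuples()
    ]


def call_peaks(
    blocks: Sequence[SignalBlock],
    threshold: float = 0.05,
    mode: str = "stringent",
    *,
    condition: str = "",
    replicate: str = "",
) -> PeakSet:
    """Retain the top ``ceil(threshold * N)`` blocks by AUC (stringent mode).

    Ties on AUC break by (chrom, start) ascending; output is
    coordinate-sorted.  An empty block list yields an empty PeakSet.
    """
    if mode != "stringent":
        raise ValueError(f"unsupported mode {mode!r}; only 'stringent'")
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if not blocks:
        return PeakSet(condition, replicate, [])
    n_keep = math.ceil(threshold * len(blocks))
    ranked = sorted(
        blocks, key=lambda b: (-b.auc, b.region.chrom, b.region.start)
    )
    return PeakSet(condition, replicate, ranked[:n_keep])


def half_mean_filter(peaks: PeakSet) -> PeakSet:
    """Drop peaks with AUC below half the file's mean AUC (single pass)."""
    if not peaks.peaks:
        return PeakSet(peaks.condition, peaks.replicate, [])
    cutoff = 0.5 * float(np.mean([p.auc for p in peaks.peaks]))
    return PeakSet(
        peaks.condition,
        peaks.replicate,
        [p for p in peaks.peaks if p.auc >= cutoff],
    )


def replicate_consensus(
    rep1: PeakSet, rep2: PeakSet, min_overlap: int = 300
) -> PeakSet:
    """Merge replicate peaks reproduced with >= ``min_overlap`` shared bases.

    Every qualifying replicate pair contributes its union span; spans that
    chain through shared peaks merge into one consensus region whose AUC is
    the sum of all distinct contributing blocks.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    a, b = rep1.peaks, rep2.peaks
    spans: list[tuple[str, int, int, int, int]] = []  # chrom, start, end, ia, ib
    i = j = 0
    while i < len(a) and j < len(b):
        ra, rb = a[i].region, b[j].region
        if ra.chrom != rb.chrom:
            if ra.chrom < rb.chrom:
                i += 1
            else:
                j += 1
            continue
        ov = min(ra.end, rb.end) - max(ra.start, rb.start)
        if ov >= min_overlap:
            spans.append(
                (ra.chrom, min(ra.start, rb.start), max(ra.end, rb.end), i, j)
            )
        if ra.end <= rb.end:
            i += 1
        else:
            j += 1
    if not spans:
        return PeakSet(rep1.condition, "consensus", [])

    spans.sort(key=lambda t: (t[0], t[1]))
    merged: list[SignalBlock] = []
    cur_chrom, cur_start, cur_end, ia_set, ib_set = (
        spans[0][0],
        spans[0][1],
        spans[0][2],
        {spans[0][3]},
        {spans[0][4]},
    )
    for chrom_, s, e, ia, ib in spans[1:]:
        if chrom_ == cur_chrom and s < cur_end:
            cur_end = max(cur_end, e)
            ia_set.add(ia)
            ib_set.add(ib)
        else:
            merged.append(_consensus_block(cur_chrom, cur_start, cur_end, a, b, ia_set, ib_set))
            cur_chrom, cur_start, cur_end = chrom_, s, e
            ia_set, ib_set = {ia}, {ib}
    merged.append(_consensus_block(cur_chrom, cur_start, cur_end, a, b, ia_set, ib_set))
    return PeakSet(rep1.condition, "consensus", merged)


def _consensus_block(
    chrom: str,
    start: int,
    end: int,
    a: list[SignalBlock],
    b: list[SignalBlock],
    ia: set[int],
    ib: set[int],
) -> SignalBlock:
    contributors = [a[i] for i in sorted(ia)] + [b[j] for j in sorted(ib)]
    return SignalBlock(
        GenomicInterval(chrom, start, end),
        sum(c.auc for c in contributors),
        max(c.max_value for c in contributors),
    )


def condition_unique(consA: PeakSet, consB: PeakSet) -> PeakSet:
    """Peaks of A with zero overlap against every peak of B."""
    unique = [
        p
        for p in consA.peaks
        if all(overlap_length(p.region, q.region) == 0 for q in consB.peaks)
    ]
    return PeakSet(consA.condition, consA.replicate, unique)


# ---------------------------------------------------------------------------
# I/O — SEACR-like peak tables
# ---------------------------------------------------------------------------

def write_peakset(path: str | Path, peaks: PeakSet) -> None:
    """Write a PeakSet as a BED6+ TSV: chrom, start, end, auc, max, name."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tauc\tmax_value\tname\n")
        for k, p in enumerate(peaks.peaks):
            r = p.region
            name = f"{peaks.condition}_{peaks.replicate}_peak{k}"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{p.auc:.6g}\t{p.max_value:.6g}\t{name}\n"
            )


def read_peakset(
    path: str | Path, condition: str = "", replicate: str = ""
) -> PeakSet:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "auc", "max_value", "name"],
        dtype={"chrom": str},
    )
    blocks = [
        SignalBlock(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            float(r.auc),
            float(r.max_value),
        )
        for r in df.itertuples()
    ]
    return PeakSet(condition, replicate, blocks)
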