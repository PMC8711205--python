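"""Count-based differential chromatin accessibility over ATAC regions.

Per region, accessibility change between a treated and a control condition is
summarised by

* a library-size-normalised fold change,
  ``FC = (mean treated CPM + c) / (mean control CPM + c)`` with pseudocount
  ``c = 0.5`` CPM, and
* a two-sided exact binomial test on pooled raw counts: with ``k`` the summed
  treated counts, ``n`` the summed counts across both conditions and
  ``pi`` the treated share of the summed library sizes, the p-value sums the
  probabilities of all outcomes no more likely than the observed one
  (minimum-likelihood convention).

Regions are classified as gained-open (p below the significance level and
FC above the fold threshold), gained-closed (FC below its reciprocal), or
unchanged.  The decision rule uses the raw p-value; a Benjamini-Hochberg
FDR column is emitted for reference only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, overlap_length, tss_window

DIRECTIONS = ("gained-open", "gained-closed", "unchanged")

PSEUDOCOUNT_CPM = 0.5


@dataclass(frozen=True)
class DifferentialThresholds:
    """Decision thresholds and the TSS restriction window."""

    p_threshold: float = 0.001
    fc_threshold: float = 4.0
    tss_up: int = 5000
    tss_down: int = 3000

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")


@dataclass
class RegionCountTable:
    """Region x sample fragment counts with per-sample library sizes.

    ``samples`` needs columns sample, condition, replicate, library_size.
    """

    regions: list[GenomicInterval]
    samples: pd.DataFrame
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape must be (n_regions, n_samples)")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(
                self.counts != np.round(self.counts)
            ):
                raise ValueError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        lib = self.samples["library_size"].to_numpy()
        if np.any(self.counts.sum(axis=0) > lib):
            raise ValueError("column sums exceed library sizes")

    def condition_columns(self, condition: str) -> np.ndarray:
        cols = np.flatnonzero(
            (self.samples["condition"] == condition).to_numpy()
        )
        if cols.size == 0:
            raise ValueError(f"no samples for condition {condition!r}")
        return cols


@dataclass(frozen=True)
class DifferentialRegion:
    """A region with its fold change, exact-test p-value and direction."""

    region: GenomicInterval
    log2fc: float
    p_value: float
    direction: str
    tested: bool = True

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")


def normalize_counts(table: RegionCountTable) -> np.ndarray:
    """Counts-per-million by sample library size."""
    lib = table.samples["library_size"].to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    return table.counts * 1e6 / lib[np.newaxis, :]


def binom_minlike_pvalue(k: int, n: int, pi: float) -> float:
    """Two-sided exact binomial p: sum of outcome probabilities <= P(k).

    A small relative slack guards against ties broken by floating-point
    noise; agrees with the minlike convention of standard exact tests.
    """
    if n == 0:
        return 1.0
    pmf = stats.binom.pmf(np.arange(n + 1), n, pi)
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()))


def exact_region_test(
    table: RegionCountTable,
    region_index: int,
    treated: str = "treated",
    control: str = "control",
) -> tuple[float, float, bool]:
    """Fold change and exact binomial p for one region.

    Returns ``(log2fc, p_value, tested)``; a region with zero counts in both
    conditions is flagged untested with ``log2fc = 0`` and ``p = 1``.
    """
    t_cols = table.condition_columns(treated)
    c_cols = table.condition_columns(control)
    cpm = normalize_counts(table)
    fc = (cpm[region_index, t_cols].mean() + PSEUDOCOUNT_CPM) / (
        cpm[region_index, c_cols].mean() + PSEUDOCOUNT_CPM
    )
    log2fc = float(np.log2(fc))

    k = int(table.counts[region_index, t_cols].sum())
    n = k + int(table.counts[region_index, c_cols].sum())
    if n == 0:
        return 0.0, 1.0, False
    lib = table.samples["library_size"].to_numpy(dtype=float)
    pi = lib[t_cols].sum() / (lib[t_cols].sum() + lib[c_cols].sum())
    return log2fc, binom_minlike_pvalue(k, n, pi), True


def differential_table(
    table: RegionCountTable,
    treated: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """Per-region log2 fold change, p-value and BH-FDR (reference only)."""
    rows = [
        exact_region_test(table, i, treated, control)
        for i in range(len(table.regions))
    ]
    df = pd.DataFrame(rows, columns=["log2fc", "p_value", "tested"])
    df["fdr_bh"] = stats.false_discovery_control(
        df["p_value"].to_numpy(), method="bh"
    )
    return df


def classify_differential(
    regions: Sequence[GenomicInterval],
    results: pd.DataFrame,
    thresholds: DifferentialThresholds = DifferentialThresholds(),
) -> list[DifferentialRegion]:
    """Apply the significance and fold-change decision rule to test results."""
    out: list[DifferentialRegion] = []
    for region, row in zip(regions, results.itertuples()):
        fc = 2.0 ** row.log2fc
        if row.p_value < thresholds.p_threshold and fc > thresholds.fc_threshold:
            direction = "gained-open"
        elif (
            row.p_value < thresholds.p_threshold
            and fc < 1.0 / thresholds.fc_threshold
        ):
            direction = "gained-closed"
        else:
            direction = "unchanged"
        out.append(
            DifferentialRegion(
                region,
                float(row.log2fc),
                float(row.p_value),
                direction,
                bool(getattr(row, "tested", True)),
            )
        )
    return out


def restrict_to_tss(
    diff: Sequence[DifferentialRegion],
    genes: Sequence[GeneModel],
    thresholds: DifferentialThresholds = DifferentialThresholds(),
) -> list[tuple[DifferentialRegion, str]]:
    """Keep regions overlapping a TSS window; one record per gene hit."""
    windows = [
        (g.gene_id, tss_window(g, thresholds.tss_up, thresholds.tss_down))
        for g in genes
    ]
    out: list[tuple[DifferentialRegion, str]] = []
    for d in diff:
        for gene_id, w in windows:
            if overlap_length(d.region, w) > 0:
                out.append((d, gene_id))
    return out


# ---------------------------------------------------------------------------
# I/O — count tables, sample sheets and differential calls
# ---------------------------------------------------------------------------

def read_region_counts(
    counts_path: str | Path, samples_path: str | Path
) -> RegionCountTable:
    """Load a region count TSV (chrom/start/end + one column per sample)
    together with its sample sheet (sample, condition, replicate,
    library_size)."""
    counts = pd.read_csv(counts_path, sep="\t", dtype={"chrom": str})
    counts.columns = [c.lstrip("#") for c in counts.columns]
    samples = pd.read_csv(samples_path, sep="\t")
    samples.columns = [c.lstrip("#") for c in samples.columns]
    regions = [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(counts["chrom"], counts["start"], counts["end"])
    ]
    mat = counts[[str(s) for s in samples["sample"]]].to_numpy()
    return RegionCountTable(regions, samples, mat)


def write_differential(
    path: str | Path, diff: Sequence[DifferentialRegion], fdr: Sequence[float] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tlog2fc\tp_value\tfdr_bh\tdirection\ttested\n")
        for i, d in enumerate(diff):
            q = fdr[i] if fdr is not None else float("nan")
            fh.write(
                f"{d.region.chrom}\t{d.region.start}\t{d.region.end}\t"
                f"{d.log2fc:.6g}\t{d.p_value:.6g}\t{q:.6g}\t{d.direction}\t"
                f"{int(d.tested)}\n"
            )


def read_differential(path: str | Path) -> list[DifferentialRegion]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df.columns = [c.lstrip("#") for c in df.columns]
    return [
        DifferentialRegion(
            GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            float(r.log2fc),
            float(r.p_value),
            str(r.direction),
            bool(int(getattr(r, "tested", 1))),
        )
        for r in df.itertuples()
    ]
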