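"""RP-HPLC quantification of linker histone H1 / nucleosome stoichiometry.

A reverse-phase HPLC trace of acid-extracted histones, monitored at 214 nm,
carries one peak per H1 subtype (H1a, H1b, H1c, H1d, H1e, H1^0) plus the
core-histone peaks.  Because A214 absorbance scales with the number of
peptide bonds, each peak area is divided by the subtype's peptide-bond count
before any molar comparison.  The nucleosome reference is the H2B peak: a
nucleosome carries two H2B copies, so the H1-per-nucleosome ratio of a
subtype is its adjusted area over half the adjusted H2B area, and total H1
per nucleosome is the corresponding sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

H2B_LABEL = "H2B"


@dataclass(frozen=True)
class Chromatogram:
    """An A214 trace on a strictly increasing retention-time grid (min)."""

    time: np.ndarray
    a214: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.a214, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and a214 must be equal-length 1-D arrays")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("a214 must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "a214", y)


@dataclass(frozen=True)
class PeakWindow:
    """A labeled retention-time window holding one subtype's peak."""

    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if not self.label:
            raise ValueError("label must be non-empty")


@dataclass(frozen=True)
class SubtypeSpec:
    """Peptide-bond count (residues - 1) used for the A214 adjustment."""

    label: str
    n_peptide_bonds: int

    def __post_init__(self) -> None:
        if self.n_peptide_bonds <= 0:
            raise ValueError("n_peptide_bonds must be positive")


@dataclass(frozen=True)
class StoichiometryResult:
    """Per-subtype and total H1/nucleosome ratios."""

    per_subtype_ratio: dict[str, float]
    total_ratio: float


def check_windows(windows: Sequence[PeakWindow]) -> None:
    """Reject overlapping windows for distinct labels."""
    ordered = sorted(windows, key=lambda w: w.t_start)
    for a, b in zip(ordered, ordered[1:]):
        if b.t_start < a.t_end:
            raise ValueError(
                f"windows {a.label!r} and {b.label!r} overlap in time"
            )


def _anchor_value(
    t: np.ndarray, y: np.ndarray, t0: float, halfwidth: float
) -> float:
    """Signal value at ``t0``, averaged over ``+-halfwidth`` to damp
    detector noise; falls back to linear interpolation when the
    neighbourhood holds no samples."""
    if halfwidth > 0:
        sel = (t >= t0 - halfwidth) & (t <= t0 + halfwidth)
        if sel.any():
            return float(y[sel].mean())
    return float(np.interp(t0, t, y))


def integrate_peak(
    chrom: Chromatogram,
    window: PeakWindow,
    baseline: str = "linear",
    baseline_halfwidth: float = 0.05,
) -> float:
    """Baseline-corrected trapezoidal peak area (mAU*min) over a window.

    With ``baseline="linear"`` (default) a straight baseline is drawn
    between the signal values at the window bounds and subtracted before
    trapezoidal integration; each bound's signal value is estimated as the
    local mean within ``baseline_halfwidth`` minutes, which keeps the
    anchor robust to detector noise (set the halfwidth to 0 for the raw
    single-sample value).  ``baseline="none"`` integrates the raw trace.
    A negative result is clipped to zero with a warning.
    """
    if baseline not in ("linear", "none"):
        raise ValueError("baseline must be 'linear' or 'none'")
    t, y = chrom.time, chrom.a214
    if window.t_start < t[0] or window.t_end > t[-1]:
        raise ValueError(
            f"window [{window.t_start}, {window.t_end}] outside the time grid"
        )
    inner = (t > window.t_start) & (t < window.t_end)
    tt = np.concatenate(([window.t_start], t[inner], [window.t_end]))
    yy = np.concatenate(
        (
            [np.interp(window.t_start, t, y)],
            y[inner],
            [np.interp(window.t_end, t, y)],
        )
    )
    if baseline == "none":
        base = np.zeros_like(tt)
    else:
        b0 = _anchor_value(t, y, window.t_start, baseline_halfwidth)
        b1 = _anchor_value(t, y, window.t_end, baseline_halfwidth)
        base = b0 + (b1 - b0) * (tt - tt[0]) / (tt[-1] - tt[0])
    baseline_arr = base
    area = float(np.trapezoid(yy - baseline_arr, tt))
    if area < 0:
        warnings.warn(
            f"negative area for window {window.label!r}; clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return area


def adjusted_area(area: float, spec: SubtypeSpec) -> float:
    """Peak area per peptide bond, the molar-comparable quantity."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return area / spec.n_peptide_bonds


def h1_nucleosome_ratios(
    areas: Mapping[str, float],
    h1_labels: Sequence[str] | set[str],
    h2b_label: str = H2B_LABEL,
) -> StoichiometryResult:
    """H1-per-nucleosome ratios from peptide-bond-adjusted areas.

    Each subtype ratio is its adjusted area over half the adjusted H2B area
    (two H2B copies per nucleosome); the total is the sum over H1 subtypes.
    """
    if h2b_label not in areas:
        raise ValueError(f"missing {h2b_label!r} area")
    h2b = areas[h2b_label]
    if h2b <= 0:
        raise ValueError(f"{h2b_label!r} area must be positive")
    missing = set(h1_labels) - set(areas)
    if missing:
        raise ValueError(f"missing H1 areas for {sorted(missing)}")
    nucleosome = h2b / 2.0
    per = {s: areas[s] / nucleosome for s in sorted(h1_labels)}
    return StoichiometryResult(per, sum(per.values()))


def percent_change(
    ratio_control: float, ratio_treated: float
) -> tuple[int, float]:
    """Relative change in percent: (integer-truncated, exact)."""
    if ratio_control <= 0:
        raise ValueError("ratio_control must be positive")
    exact = 100.0 * (ratio_treated - ratio_control) / ratio_control
    return math.trunc(exact), exact


def quantify_sample(
    chrom: Chromatogram,
    windows: Sequence[PeakWindow],
    subtypes: Sequence[SubtypeSpec],
    h2b_label: str = H2B_LABEL,
) -> StoichiometryResult:
    """Full per-sample pipeline: integrate, bond-adjust, form ratios."""
    check_windows(windows)
    specs = {s.label: s for s in subtypes}
    missing = {w.label for w in windows} - set(specs)
    if missing:
        raise ValueError(f"no peptide-bond spec for {sorted(missing)}")
    adj = {
        w.label: adjusted_area(integrate_peak(chrom, w), specs[w.label])
        for w in windows
    }
    h1_labels = [w.label for w in windows if w.label != h2b_label]
    return h1_nucleosome_ratios(adj, h1_labels, h2b_label)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_chromatogram(path: str | Path) -> Chromatogram:
    """Two-column trace (time, a214); TSV or CSV, optional '#' header."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    return Chromatogram(
        df[0].to_numpy(dtype=float), df[1].to_numpy(dtype=float)
    )


def read_windows(path: str | Path) -> list[PeakWindow]:
    """Window table TSV: label, t_start, t_end."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["label", "t_start", "t_end"], dtype={"label": str},
    )
    return [
        PeakWindow(str(r.label), float(r.t_start), float(r.t_end))
        for r in df.itertuples()
    ]


def read_subtypes(path: str | Path) -> list[SubtypeSpec]:
    """Subtype spec TSV: label, residues (bonds = residues - 1)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["label", "residues"], dtype={"label": str},
    )
    return [
        SubtypeSpec(str(r.label), int(r.residues) - 1) for r in df.itertuples()
    ]


def write_stoichiometry(
    path: str | Path, results: Mapping[str, StoichiometryResult]
) -> None:
    """One row per (sample, subtype) plus a total row per sample."""
    with open(path, "w") as fh:
        fh.write("#sample\tlabel\tratio\n")
        for sample in sorted(results):
            res = results[sample]
            for label in sorted(res.per_subtype_ratio):
                fh.write(
                    f"{sample}\t{label}\t{res.per_subtype_ratio[label]:.6g}\n"
                )
            fh.write(f"{sample}\ttotal_H1\t{res.total_ratio:.6g}\n")
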