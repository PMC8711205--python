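"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of the assays the pipeline
analyses — multi-replicate CUT&RUN coverage with planted enriched blocks
over sparse Poisson background, negative-binomial ATAC region counts with
planted fold changes, strand-aware gene/TE annotations, and Gaussian-peak
RP-HPLC chromatograms with known analytic areas — and record the planted
truth in a manifest so that recovery can be scored exactly.

Every generator is a pure function of :class:`SimulationConfig`: the same
seed yields byte-identical outputs.  Each generator draws from its own
pseudo-random stream derived from the master seed by a fixed offset, so
adding a generator never perturbs existing outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import DifferentialRegion, RegionCountTable
from .h1quant import Chromatogram, PeakWindow, SubtypeSpec
from .intervals import (
    GeneModel,
    GenomicInterval,
    overlap_length,
    tss_window,
    write_gene_table,
)
from .annotation import TE_CLASSES, TEAnnotation, write_te_table
from .peakcalling import PeakSet, SignalBlock

CONDITIONS = ("control", "treated")

# fixed sub-stream offsets (never renumber: reproducibility contract)
_STREAM_ANNOTATION = 1
_STREAM_BLOCK_PLAN = 2
_STREAM_BEDGRAPH = 3
_STREAM_COUNTS = 4
_STREAM_CHROMATOGRAM = 5


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

# Mouse linker-histone subtype and H2B residue counts (mature chains),
# used only to exercise the peptide-bond adjustment with realistic scale.
DEFAULT_RESIDUES = {
    "H1a": 213,
    "H1b": 224,
    "H1c": 212,
    "H1d": 221,
    "H1e": 219,
    "H1^0": 194,
    "H2B": 126,
}

# Molar amounts relative to H2B = 1.0.  The control amounts sum to 0.29 so
# that total H1 per nucleosome is 0.29 / (1.0 / 2) = 0.58; the treated
# amounts sum to 0.335 (ratio 0.67), with H1a/H1b/H1e/H1^0 up, H1d down and
# H1c unchanged — the qualitative subtype pattern of HDACi-treated mESCs.
DEFAULT_AMOUNTS = {
    "control": {
        "H1a": 0.030, "H1b": 0.050, "H1c": 0.070,
        "H1d": 0.080, "H1e": 0.050, "H1^0": 0.010, "H2B": 1.0,
    },
    "treated": {
        "H1a": 0.045, "H1b": 0.065, "H1c": 0.070,
        "H1d": 0.060, "H1e": 0.080, "H1^0": 0.015, "H2B": 1.0,
    },
}

DEFAULT_CENTERS = {
    "H1a": 32.0, "H1b": 34.0, "H1c": 36.0,
    "H1d": 38.0, "H1e": 40.0, "H1^0": 42.0, "H2B": 47.0,
}


@dataclass(frozen=True)
class ChromatogramSpec:
    """Shape of the synthetic RP-HPLC traces.

    Peak areas are ``amount x peptide bonds`` so that bond-adjusted areas
    recover molar amounts exactly; noise and baseline drift are expressed
    as fractions of the tallest peak height.
    """

    amounts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            c: dict(DEFAULT_AMOUNTS[c]) for c in CONDITIONS
        }
    )
    residues: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUES)
    )
    centers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENTERS)
    )
    sigma: float = 0.15  # peak width (min)
    t_start: float = 28.0
    t_end: float = 50.0
    dt: float = 0.005  # grid step (min)
    noise_sigma_frac: float = 3e-4  # of max peak height (~0.1 mAU detector)
    baseline_drift_frac: float = 0.01  # drift over the run, of max height
    baseline_offset: float = 1.0  # mAU
    window_halfwidth_sigmas: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the defaults the tests use."""

    seed: int = 0
    # genome shape
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    # annotation density
    n_genes: int = 200
    n_tes: int = 400
    # CUT&RUN signal model
    n_planted_enriched: int = 30  # shared enriched blocks per condition
    enrichment_fold: float = 10.0
    background_rate: float = 0.5  # mean bedGraph value per bin
    bin_width: int = 10
    block_width: int = 800
    n_replicates: int = 2
    # ATAC count model
    n_regions: int = 2000
    region_width: int = 500
    depth_mean: float = 50.0
    nb_dispersion: float = 0.001  # var = mu * (1 + alpha * mu)
    n_planted_diff: int = 100  # planted regions beyond the category genes
    planted_fc: float = 8.0
    # integration structure
    planted_categories: dict[str, int] = field(
        default_factory=lambda: {"I": 11, "II": 73, "III": 5}
    )
    chromatogram: ChromatogramSpec = field(default_factory=ChromatogramSpec)

    def __post_init__(self) -> None:
        if self.enrichment_fold <= 1:
            raise ValueError("enrichment_fold must exceed 1")
        if any(v < 0 for v in self.planted_categories.values()):
            raise ValueError("planted category counts must be >= 0")
        if sum(self.planted_categories.values()) > self.n_genes:
            raise ValueError("more planted category genes than genes")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


# ---------------------------------------------------------------------------
# Truth manifest
# ---------------------------------------------------------------------------

@dataclass
class TruthManifest:
    """Everything planted, matchable to pipeline output by coordinates."""

    genes: list[GeneModel] = field(default_factory=list)
    tes: list[TEAnnotation] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)  # gene -> cat
    # per condition: (interval, kind in {shared, unique}, gene_id or None)
    cutrun_blocks: dict[str, list[tuple[GenomicInterval, str, str | None]]] = (
        field(default_factory=dict)
    )
    # (region index, interval, direction, gene_id or None)
    diff_regions: list[tuple[int, GenomicInterval, str, str | None]] = field(
        default_factory=list
    )
    # per condition: label -> (true area, true amount)
    chromatogram_truth: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )

    def to_json(self, path: str | Path) -> None:
        def iv(i: GenomicInterval) -> list:
            return [i.chrom, i.start, i.end]

        doc = {
            "genes": [
                [g.gene_id, g.body.chrom, g.body.start, g.body.end,
                 g.body.strand]
                for g in self.genes
            ],
            "tes": [iv(t.region) + [t.te_class] for t in self.tes],
            "categories": self.categories,
            "cutrun_blocks": {
                cond: [iv(b) + [kind, gid] for b, kind, gid in blocks]
                for cond, blocks in self.cutrun_blocks.items()
            },
            "diff_regions": [
                [idx] + iv(r) + [direction, gid]
                for idx, r, direction, gid in self.diff_regions
            ],
            "chromatogram_truth": self.chromatogram_truth,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_annotation(
    cfg: SimulationConfig,
) -> tuple[list[GeneModel], list[TEAnnotation]]:
    """Non-overlapping stranded genes on a slot grid, plus random TEs.

    Each gene lives in its own slot with margins wide enough that TSS
    windows of neighbouring genes cannot overlap.
    """
    rng = _rng(cfg.seed, _STREAM_ANNOTATION)
    chroms = cfg.chrom_names()
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1

    margin = 7000  # > max(tss_up, tss_down + 1): windows stay in-slot
    min_len, max_len = 2000, 6000
    genes: list[GeneModel] = []
    k = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = cfg.chrom_length // n_here
        if slot < 2 * margin + max_len:
            raise ValueError(
                "chrom_length too small to place genes without "
                "overlapping TSS windows"
            )
        for j in range(n_here):
            lo = j * slot
            length = int(rng.integers(min_len, max_len + 1))
            start = int(
                rng.integers(lo + margin, lo + slot - margin - length + 1)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    f"gene{k:04d}",
                    GenomicInterval(chrom, start, start + length, strand),
                )
            )
            k += 1

    tes: list[TEAnnotation] = []
    for _ in range(cfg.n_tes):
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        length = int(rng.integers(300, 3001))
        start = int(rng.integers(0, cfg.chrom_length - length))
        tes.append(
            TEAnnotation(
                GenomicInterval(chrom, start, start + length),
                TE_CLASSES[int(rng.integers(len(TE_CLASSES)))],
            )
        )
    return genes, tes


def assign_categories(
    cfg: SimulationConfig, genes: Sequence[GeneModel]
) -> dict[str, str]:
    """Deterministically pick which genes carry each planted category."""
    rng = _rng(cfg.seed, _STREAM_ANNOTATION, 1)
    order = rng.permutation(len(genes))
    categories: dict[str, str] = {}
    i = 0
    for cat in sorted(cfg.planted_categories):
        for _ in range(cfg.planted_categories[cat]):
            categories[genes[order[i]].gene_id] = cat
            i += 1
    return categories


# ---------------------------------------------------------------------------
# CUT&RUN coverage tracks
# ---------------------------------------------------------------------------

def plan_cutrun_blocks(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    categories: dict[str, str],
) -> dict[str, list[tuple[GenomicInterval, str, str | None]]]:
    """Where the enriched blocks go, per condition.

    Category I and III genes get a treated-unique block over the TSS,
    category II genes a control-unique block; ``n_planted_enriched`` shared
    blocks appear in both conditions away from all unique blocks and all
    TSS windows.
    """
    rng = _rng(cfg.seed, _STREAM_BLOCK_PLAN)
    by_id = {g.gene_id: g for g in genes}
    width = cfg.block_width

    unique: dict[str, list[tuple[GenomicInterval, str, str | None]]] = {
        c: [] for c in CONDITIONS
    }
    keep_out: list[GenomicInterval] = [
        tss_window(g, 5000, 3000) for g in genes
    ]
    for gene_id, cat in sorted(categories.items()):
        g = by_id[gene_id]
        start = max(0, g.tss - width // 2)
        block = GenomicInterval(g.body.chrom, start, start + width)
        cond = "control" if cat == "II" else "treated"
        if cat in ("I", "II", "III"):
            unique[cond].append((block, "unique", gene_id))
            keep_out.append(block)

    chroms = cfg.chrom_names()
    shared: list[tuple[GenomicInterval, str, str | None]] = []
    attempts = 0
    while len(shared) < cfg.n_planted_enriched:
        attempts += 1
        if attempts > 10000 * max(1, cfg.n_planted_enriched):
            raise ValueError("cannot place shared blocks without collisions")
        chrom = chroms[int(rng.integers(cfg.n_chroms))]
        start = int(rng.integers(0, cfg.chrom_length - width))
        cand = GenomicInterval(chrom, start, start + width)
        if any(overlap_length(cand, k) > 0 for k in keep_out):
            continue
        keep_out.append(cand)
        shared.append((cand, "shared", None))

    return {c: sorted(unique[c] + shared, key=lambda t: (t[0].chrom, t[0].start))
            for c in CONDITIONS}


def _bins_to_bedgraph(
    chrom: str, values: np.ndarray, bin_width: int
) -> pd.DataFrame:
    """Run-length encode nonzero equal-valued bin runs as bedGraph rows."""
    nz = np.flatnonzero(values)
    if nz.size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    brk = np.ones(nz.size, dtype=bool)
    brk[1:] = (np.diff(nz) != 1) | (values[nz[1:]] != values[nz[:-1]])
    run_start = nz[brk]
    run_id = np.cumsum(brk) - 1
    run_len = np.bincount(run_id)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": run_start * bin_width,
            "end": (run_start + run_len) * bin_width,
            "value": values[run_start],
        }
    )


def simulate_bedgraph(
    cfg: SimulationConfig, condition: str, replicate: int
) -> tuple[pd.DataFrame, list[tuple[GenomicInterval, str, str | None]]]:
    """One replicate coverage track: Poisson background plus planted blocks.

    Background bins draw Poisson(``background_rate``); bins inside a
    planted block draw Poisson(rate x ``enrichment_fold``).  Replicates
    share block locations and differ only in noise.  Returns the bedGraph
    records and this condition's manifest block entries.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    genes, _ = make_annotation(cfg)
    categories = assign_categories(cfg, genes)
    plan = plan_cutrun_blocks(cfg, genes, categories)
    blocks = plan[condition]

    cond_idx = CONDITIONS.index(condition)
    rng = _rng(cfg.seed, _STREAM_BEDGRAPH, cond_idx, replicate)
    n_bins = cfg.chrom_length // cfg.bin_width
    # with a zero background the fold has nothing to multiply; the planted
    # rate then equals the fold itself so blocks remain the only signal
    enriched_rate = (
        cfg.background_rate * cfg.enrichment_fold
        if cfg.background_rate > 0
        else cfg.enrichment_fold
    )
    frames = []
    for chrom in cfg.chrom_names():
        lam = np.full(n_bins, cfg.background_rate)
        for block, _, _ in blocks:
            if block.chrom == chrom:
                b0 = block.start // cfg.bin_width
                b1 = -(-block.end // cfg.bin_width)
                lam[b0:b1] = enriched_rate
        values = rng.poisson(lam)
        frames.append(_bins_to_bedgraph(chrom, values, cfg.bin_width))
    track = pd.concat(frames, ignore_index=True)
    return track, blocks


# ---------------------------------------------------------------------------
# ATAC region counts
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, alpha: float
) -> np.ndarray:
    """NB with var = mu (1 + alpha mu); alpha -> 0 is Poisson."""
    if alpha <= 0:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[RegionCountTable, list[tuple[int, GenomicInterval, str, str | None]]]:
    """Region x sample NB counts with planted fold changes.

    Category-gene regions sit over the gene's TSS (gained-open for I,
    gained-closed for II/III); ``n_planted_diff`` further planted regions
    (half open, half closed) and background regions fill a genome-wide
    slot grid.  Library sizes are the column sums.
    """
    rng = _rng(cfg.seed, _STREAM_COUNTS)
    genes, _ = make_annotation(cfg)
    categories = assign_categories(cfg, genes)
    by_id = {g.gene_id: g for g in genes}
    width = cfg.region_width

    planted: list[tuple[GenomicInterval, str, str | None]] = []
    for gene_id, cat in sorted(categories.items()):
        g = by_id[gene_id]
        start = max(0, g.tss - width // 2)
        region = GenomicInterval(g.body.chrom, start, start + width)
        direction = "gained-open" if cat in ("I", "IV") else "gained-closed"
        planted.append((region, direction, gene_id))

    # slot grid for the remaining regions
    chroms = cfg.chrom_names()
    n_rest = cfg.n_regions - len(planted)
    if n_rest < cfg.n_planted_diff:
        raise ValueError("n_regions too small for the planted structure")
    slot = (cfg.n_chroms * cfg.chrom_length) // cfg.n_regions
    if slot <= width:
        raise ValueError("n_regions too dense for the genome size")
    slots_per_chrom = cfg.chrom_length // slot
    all_slots = [
        (c, s) for c in chroms for s in range(slots_per_chrom)
    ]
    taken = [r for r, _, _ in planted]
    # extra planted (directional) regions stay out of the category genes'
    # TSS windows so they cannot override a planted category's direction;
    # unchanged background regions may fall anywhere
    category_windows = [
        tss_window(by_id[gid], 5000, 3000) for gid in sorted(categories)
    ]
    extra_planted: list[GenomicInterval] = []
    background: list[GenomicInterval] = []
    for c, s in (all_slots[i] for i in rng.permutation(len(all_slots))):
        if len(extra_planted) == cfg.n_planted_diff and (
            len(background) == n_rest - cfg.n_planted_diff
        ):
            break
        off = int(rng.integers(0, slot - width))
        cand = GenomicInterval(c, s * slot + off, s * slot + off + width)
        if any(overlap_length(cand, t) > 0 for t in taken):
            continue
        if len(extra_planted) < cfg.n_planted_diff and not any(
            overlap_length(cand, w) > 0 for w in category_windows
        ):
            extra_planted.append(cand)
        elif len(background) < n_rest - cfg.n_planted_diff:
            background.append(cand)
    if len(extra_planted) < cfg.n_planted_diff or (
        len(background) < n_rest - cfg.n_planted_diff
    ):
        raise ValueError("could not place background regions")

    n_extra_open = cfg.n_planted_diff // 2
    for i, r in enumerate(extra_planted):
        direction = "gained-open" if i < n_extra_open else "gained-closed"
        planted.append((r, direction, None))

    regions = [r for r, _, _ in planted] + background
    directions = [d for _, d, _ in planted] + ["unchanged"] * len(background)
    gene_ids = [g for _, _, g in planted] + [None] * len(background)

    n_samples = 2 * cfg.n_replicates
    base = np.full(len(regions), cfg.depth_mean)
    mean = np.tile(base[:, None], (1, n_samples)).astype(float)
    treated_cols = list(range(cfg.n_replicates, n_samples))
    for i, d in enumerate(directions):
        if d == "gained-open":
            mean[i, treated_cols] *= cfg.planted_fc
        elif d == "gained-closed":
            mean[i, treated_cols] /= cfg.planted_fc
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    samples = pd.DataFrame(
        {
            "sample": [
                f"{cond}_r{r + 1}"
                for cond in CONDITIONS
                for r in range(cfg.n_replicates)
            ],
            "condition": [
                cond for cond in CONDITIONS for _ in range(cfg.n_replicates)
            ],
            "replicate": [
                f"r{r + 1}" for _ in CONDITIONS for r in range(cfg.n_replicates)
            ],
            "library_size": counts.sum(axis=0),
        }
    )
    table = RegionCountTable(regions, samples, counts)
    manifest = [
        (i, regions[i], directions[i], gene_ids[i])
        for i in range(len(regions))
        if directions[i] != "unchanged"
    ]
    return table, manifest


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

def simulate_chromatogram(
    cfg: SimulationConfig, condition: str
) -> tuple[Chromatogram, list[PeakWindow], list[SubtypeSpec],
           dict[str, tuple[float, float]]]:
    """Sum-of-Gaussians A214 trace with known analytic areas.

    Raw peak areas are ``amount x peptide bonds`` so the bond adjustment
    recovers molar amounts; a linear baseline and additive Gaussian noise
    are superimposed.  Returns the trace, the peak windows, the subtype
    specs and the truth map label -> (area, amount).
    """
    spec = cfg.chromatogram
    if condition not in spec.amounts:
        raise ValueError(f"no amounts for condition {condition!r}")
    amounts = spec.amounts[condition]
    cond_idx = CONDITIONS.index(condition)
    rng = _rng(cfg.seed, _STREAM_CHROMATOGRAM, cond_idx)

    labels = sorted(amounts)
    centers = [spec.centers[lab] for lab in labels]
    for a, b in zip(sorted(centers), sorted(centers)[1:]):
        if b - a < 4 * spec.sigma:
            raise ValueError("peak centers must be >= 4 sigma apart")

    t = np.arange(spec.t_start, spec.t_end + spec.dt / 2, spec.dt)
    signal = np.zeros_like(t)
    truth: dict[str, tuple[float, float]] = {}
    heights = []
    for lab in labels:
        bonds = spec.residues[lab] - 1
        area = amounts[lab] * bonds
        h = area / (spec.sigma * np.sqrt(2 * np.pi))
        heights.append(h)
        signal += h * np.exp(
            -0.5 * ((t - spec.centers[lab]) / spec.sigma) ** 2
        )
        truth[lab] = (area, amounts[lab])
    hmax = max(heights)
    slope = spec.baseline_drift_frac * hmax / (spec.t_end - spec.t_start)
    signal += spec.baseline_offset + slope * (t - spec.t_start)
    signal += rng.normal(0.0, spec.noise_sigma_frac * hmax, size=t.shape)

    hw = spec.window_halfwidth_sigmas * spec.sigma
    windows = [
        PeakWindow(lab, spec.centers[lab] - hw, spec.centers[lab] + hw)
        for lab in labels
    ]
    subtypes = [
        SubtypeSpec(lab, spec.residues[lab] - 1) for lab in labels
    ]
    return Chromatogram(t, signal), windows, subtypes, truth


# ---------------------------------------------------------------------------
# Integration inputs with unambiguous evidence
# ---------------------------------------------------------------------------

def simulate_integration_inputs(
    cfg: SimulationConfig,
) -> tuple[
    list[tuple[DifferentialRegion, str]],
    PeakSet,
    PeakSet,
    list[GeneModel],
    dict[str, str],
]:
    """Noise-free integration inputs planted per ``planted_categories``.

    Builds TSS-restricted differential records and condition-unique peak
    sets directly from the planted truth, so the downstream classification
    is exercised deterministically.
    """
    genes, _ = make_annotation(cfg)
    categories = assign_categories(cfg, genes)
    by_id = {g.gene_id: g for g in genes}

    atac: list[tuple[DifferentialRegion, str]] = []
    treated_blocks: list[SignalBlock] = []
    control_blocks: list[SignalBlock] = []
    width = cfg.block_width
    for gene_id, cat in sorted(categories.items()):
        g = by_id[gene_id]
        start = max(0, g.tss - width // 2)
        region = GenomicInterval(g.body.chrom, start, start + width)
        direction = "gained-open" if cat in ("I", "IV") else "gained-closed"
        lfc = 3.0 if direction == "gained-open" else -3.0
        atac.append(
            (DifferentialRegion(region, lfc, 1e-6, direction), gene_id)
        )
        block = SignalBlock(region, 1000.0, 10.0)
        if cat in ("I", "III"):
            treated_blocks.append(block)
        elif cat == "II":
            control_blocks.append(block)
        else:  # IV
            control_blocks.append(block)
    return (
        atac,
        PeakSet("treated", "consensus", treated_blocks),
        PeakSet("control", "consensus", control_blocks),
        genes,
        categories,
    )


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def simulate_bundle(cfg: SimulationConfig, outdir: str | Path) -> TruthManifest:
    """Emit every pipeline input into ``outdir`` plus the truth manifest.

    Files: gene/TE tables, one bedGraph per condition x replicate, the
    ATAC count table and sample sheet, one chromatogram + window + subtype
    table per condition, and ``truth.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = TruthManifest()

    genes, tes = make_annotation(cfg)
    manifest.genes, manifest.tes = genes, tes
    manifest.categories = assign_categories(cfg, genes)
    write_gene_table(out / "genes.tsv", genes)
    write_te_table(out / "tes.tsv", tes)

    for condition in CONDITIONS:
        for rep in range(cfg.n_replicates):
            track, blocks = simulate_bedgraph(cfg, condition, rep)
            track.to_csv(
                out / f"cutrun_{condition}_r{rep + 1}.bedgraph",
                sep="\t", header=False, index=False,
            )
            manifest.cutrun_blocks[condition] = blocks

    table, diff_manifest = simulate_counts(cfg)
    manifest.diff_regions = diff_manifest
    counts_df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in table.regions],
            "start": [r.start for r in table.regions],
            "end": [r.end for r in table.regions],
        }
    )
    for j, name in enumerate(table.samples["sample"]):
        counts_df[name] = table.counts[:, j]
    counts_df.rename(columns={"chrom": "#chrom"}).to_csv(
        out / "atac_counts.tsv", sep="\t", index=False
    )
    table.samples.rename(columns={"sample": "#sample"}).to_csv(
        out / "atac_samples.tsv", sep="\t", index=False
    )

    for condition in CONDITIONS:
        chrom, windows, subtypes, truth = simulate_chromatogram(cfg, condition)
        pd.DataFrame({"t": chrom.time, "a214": chrom.a214}).to_csv(
            out / f"hplc_{condition}.tsv", sep="\t",
            header=False, index=False, float_format="%.6g",
        )
        with open(out / f"hplc_windows_{condition}.tsv", "w") as fh:
            fh.write("#label\tt_start\tt_end\n")
            for w in windows:
                fh.write(f"{w.label}\t{w.t_start:.6g}\t{w.t_end:.6g}\n")
        with open(out / f"hplc_subtypes_{condition}.tsv", "w") as fh:
            fh.write("#label\tresidues\n")
            for s in subtypes:
                fh.write(f"{s.label}\t{s.n_peptide_bonds + 1}\n")
        manifest.chromatogram_truth[condition] = truth

    manifest.to_json(out / "truth.json")
    return manifest


def config_from_dict(doc: dict) -> SimulationConfig:
    """Build a SimulationConfig from a flat mapping (YAML-friendly)."""
    doc = dict(doc)
    chrom_spec = doc.pop("chromatogram", None)
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(doc) - fields
    if unknown:
        raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
    if chrom_spec is not None:
        doc["chromatogram"] = ChromatogramSpec(**chrom_spec)
    return SimulationConfig(**doc)
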