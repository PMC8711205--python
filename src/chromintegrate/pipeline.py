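"""End-to-end orchestration: peak calling -> differential -> annotation ->
integration -> H1 stoichiometry, with a machine-readable run log.

Stages are independently skippable: any stage whose inputs are absent from
the configuration is skipped, and downstream stages degrade accordingly
(e.g. without CUT&RUN input every integration call is ``uncalled``).
All tabular outputs are tab-separated with a single '#'-prefixed header
line; report numbers are written only to files, never parsed from logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .annotation import (
    assign_genes,
    feature_fractions,
    read_te_table,
    te_overlap_proportions,
    write_assignments,
    write_te_proportions,
)
from .differential import (
    DifferentialThresholds,
    classify_differential,
    differential_table,
    read_region_counts,
    restrict_to_tss,
    write_differential,
)
from .h1quant import (
    percent_change,
    quantify_sample,
    read_chromatogram,
    read_subtypes,
    read_windows,
    write_stoichiometry,
)
from .integration import (
    category_counts,
    integrate_at_tss,
    write_category_counts,
    write_integration,
)
from .intervals import read_bedgraph, read_gene_table
from .peakcalling import (
    PeakSet,
    call_peaks,
    condition_unique,
    half_mean_filter,
    replicate_consensus,
    segment_signal_blocks,
    write_peakset,
)

log = logging.getLogger("chromintegrate")


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; defaults are the analysis set
    the pipeline was designed around (SEACR threshold 0.05, 300 bp
    consensus overlap, p < 0.001 with 4-fold change, TSS -5000/+3000,
    10 kb genebody flank)."""

    outdir: str
    genes: str | None = None
    te_table: str | None = None
    # CUT&RUN bedGraphs per condition, one per replicate
    cutrun_control: list[str] = field(default_factory=list)
    cutrun_treated: list[str] = field(default_factory=list)
    # ATAC counts
    atac_counts: str | None = None
    atac_samples: str | None = None
    # HPLC traces
    hplc_control: str | None = None
    hplc_treated: str | None = None
    hplc_windows_control: str | None = None
    hplc_windows_treated: str | None = None
    hplc_subtypes_control: str | None = None
    hplc_subtypes_treated: str | None = None
    # parameters
    peak_threshold: float = 0.05
    peak_mode: str = "stringent"
    min_overlap: int = 300
    genebody_flank: int = 10000
    thresholds: DifferentialThresholds = field(
        default_factory=DifferentialThresholds
    )
    te_denominator: str = "te-overlapped"
    seed: int = 0

    def to_dict(self) -> dict:
        doc = dataclasses.asdict(self)
        doc["thresholds"] = dataclasses.asdict(self.thresholds)
        # the output location does not influence any result
        doc.pop("outdir")
        return doc


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _call_condition(
    cfg: PipelineConfig, condition: str, paths: list[str], outdir: Path
) -> PeakSet:
    reps = []
    for i, p in enumerate(paths):
        track = read_bedgraph(p)
        blocks = segment_signal_blocks(track)
        peaks = call_peaks(
            blocks,
            cfg.peak_threshold,
            cfg.peak_mode,
            condition=condition,
            replicate=f"r{i + 1}",
        )
        peaks = half_mean_filter(peaks)
        write_peakset(outdir / f"peaks_{condition}_r{i + 1}.tsv", peaks)
        log.info("%s r%d: %d peaks after half-mean filter",
                 condition, i + 1, len(peaks))
        reps.append(peaks)
    if len(reps) == 1:
        consensus = PeakSet(condition, "consensus", reps[0].peaks)
    else:
        consensus = reps[0]
        for other in reps[1:]:
            consensus = replicate_consensus(consensus, other, cfg.min_overlap)
    write_peakset(outdir / f"peaks_{condition}_consensus.tsv", consensus)
    log.info("%s: %d consensus peaks", condition, len(consensus))
    return consensus


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; returns a summary dictionary.

    Per-stage failures raise with a stage-named message; outputs written
    before the failure are retained in ``outdir``.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    inputs = {
        k: v
        for k, v in {
            "genes": cfg.genes,
            "te_table": cfg.te_table,
            "atac_counts": cfg.atac_counts,
            "atac_samples": cfg.atac_samples,
            "hplc_control": cfg.hplc_control,
            "hplc_treated": cfg.hplc_treated,
        }.items()
        if v
    }
    for i, p in enumerate(cfg.cutrun_control):
        inputs[f"cutrun_control_r{i + 1}"] = p
    for i, p in enumerate(cfg.cutrun_treated):
        inputs[f"cutrun_treated_r{i + 1}"] = p

    genes = read_gene_table(cfg.genes) if cfg.genes else []

    # ---- CUT&RUN peak calling --------------------------------------------
    unique_treated = PeakSet("treated", "consensus", [])
    unique_control = PeakSet("control", "consensus", [])
    if cfg.cutrun_control and cfg.cutrun_treated:
        try:
            cons_c = _call_condition(
                cfg, "control", cfg.cutrun_control, outdir
            )
            cons_t = _call_condition(
                cfg, "treated", cfg.cutrun_treated, outdir
            )
            unique_treated = condition_unique(cons_t, cons_c)
            unique_control = condition_unique(cons_c, cons_t)
            write_peakset(outdir / "peaks_treated_unique.tsv", unique_treated)
            write_peakset(outdir / "peaks_control_unique.tsv", unique_control)
            summary["peaks"] = {
                "control_consensus": len(cons_c),
                "treated_consensus": len(cons_t),
                "control_unique": len(unique_control),
                "treated_unique": len(unique_treated),
            }
        except Exception as exc:
            raise RuntimeError(f"peakcalling stage failed: {exc}") from exc
    else:
        log.info("peakcalling stage skipped (no CUT&RUN inputs)")

    # ---- ATAC differential accessibility ---------------------------------
    diff = []
    atac_tss: list = []
    if cfg.atac_counts and cfg.atac_samples:
        try:
            table = read_region_counts(cfg.atac_counts, cfg.atac_samples)
            results = differential_table(table)
            diff = classify_differential(
                table.regions, results, cfg.thresholds
            )
            write_differential(
                outdir / "atac_differential.tsv",
                diff,
                results["fdr_bh"].to_numpy(),
            )
            directional = [d for d in diff if d.direction != "unchanged"]
            if genes:
                atac_tss = restrict_to_tss(directional, genes, cfg.thresholds)
            summary["differential"] = {
                "n_regions": len(diff),
                "gained_open": sum(
                    d.direction == "gained-open" for d in diff
                ),
                "gained_closed": sum(
                    d.direction == "gained-closed" for d in diff
                ),
                "n_tss_records": len(atac_tss),
            }
            log.info(
                "differential: %d open / %d closed of %d regions",
                summary["differential"]["gained_open"],
                summary["differential"]["gained_closed"],
                len(diff),
            )
        except Exception as exc:
            raise RuntimeError(f"differential stage failed: {exc}") from exc
    else:
        log.info("differential stage skipped (no ATAC inputs)")

    # ---- Annotation -------------------------------------------------------
    if genes and (len(unique_treated) or len(unique_control)):
        try:
            merged = PeakSet(
                "both", "unique", unique_treated.peaks + unique_control.peaks
            )
            assignments = assign_genes(merged, genes, cfg.genebody_flank)
            write_assignments(outdir / "peak_annotation.tsv", assignments)
            fractions = feature_fractions(assignments)
            summary["feature_fractions"] = fractions
        except Exception as exc:
            raise RuntimeError(f"annotation stage failed: {exc}") from exc
    if cfg.te_table and diff:
        try:
            tes = read_te_table(cfg.te_table)
            directional = [d for d in diff if d.direction != "unchanged"]
            props = te_overlap_proportions(
                directional, tes, cfg.te_denominator
            )
            write_te_proportions(outdir / "te_proportions.tsv", props)
            summary["n_te_classes"] = len(props)
        except Exception as exc:
            raise RuntimeError(f"TE annotation stage failed: {exc}") from exc

    # ---- Integration ------------------------------------------------------
    if genes:
        try:
            calls = integrate_at_tss(
                atac_tss, unique_treated, unique_control, genes,
                cfg.thresholds,
            )
            counts = category_counts(calls)
            write_integration(outdir / "integration_calls.tsv", calls)
            write_category_counts(outdir / "integration_counts.tsv", counts)
            summary["integration"] = counts
            log.info("integration: %s", counts)
        except Exception as exc:
            raise RuntimeError(f"integration stage failed: {exc}") from exc

    # ---- H1 stoichiometry -------------------------------------------------
    if cfg.hplc_control and cfg.hplc_treated:
        try:
            results = {}
            for cond, trace, wins, subs in (
                ("control", cfg.hplc_control, cfg.hplc_windows_control,
                 cfg.hplc_subtypes_control),
                ("treated", cfg.hplc_treated, cfg.hplc_windows_treated,
                 cfg.hplc_subtypes_treated),
            ):
                results[cond] = quantify_sample(
                    read_chromatogram(trace),
                    read_windows(wins),
                    read_subtypes(subs),
                )
            write_stoichiometry(outdir / "h1_stoichiometry.tsv", results)
            pct_int, pct_exact = percent_change(
                results["control"].total_ratio,
                results["treated"].total_ratio,
            )
            with open(outdir / "h1_comparison.tsv", "w") as fh:
                fh.write(
                    "#total_control\ttotal_treated\tpercent_change\t"
                    "percent_change_exact\n"
                )
                fh.write(
                    f"{results['control'].total_ratio:.6g}\t"
                    f"{results['treated'].total_ratio:.6g}\t"
                    f"{pct_int}\t{pct_exact:.6g}\n"
                )
            summary["h1"] = {
                "total_control": results["control"].total_ratio,
                "total_treated": results["treated"].total_ratio,
                "percent_change": pct_int,
            }
            log.info("H1/nucleosome: %s", summary["h1"])
        except Exception as exc:
            raise RuntimeError(f"h1_quant stage failed: {exc}") from exc
    else:
        log.info("h1_quant stage skipped (no HPLC inputs)")

    run_log = {
        "package": "chromintegrate",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "parameters": cfg.to_dict(),
        "input_checksums": {k: _sha256(v) for k, v in sorted(inputs.items())},
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=1, sort_keys=True)
    summary["outdir"] = str(outdir)
    return summary
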