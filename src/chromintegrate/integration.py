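"""Joint ATAC x H3K56ac classification at transcription start sites.

Each gene's TSS window is scored on two axes: the direction of its
differential ATAC accessibility and the presence of condition-unique
H3K56ac consensus peaks (treated-unique peak over the window = acetylation
gain; control-unique peak = loss).  The joint state maps to four
categories:

* I    gain accessibility and gain H3K56ac
* II   lose accessibility and lose H3K56ac
* III  lose accessibility while gaining H3K56ac
* IV   gain accessibility while losing H3K56ac (the logically remaining
       quadrant, reported for completeness and flagged as such)

Genes missing either line of evidence, or with contradictory H3K56ac
evidence (both a treated- and a control-unique peak over the window), are
left uncalled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .differential import DifferentialRegion, DifferentialThresholds
from .intervals import GeneModel, overlap_length, tss_window
from .peakcalling import PeakSet, SignalBlock

CATEGORIES = ("I", "II", "III", "IV", "uncalled")

#: The quadrant not part of the original three-way enumeration.
EXTRA_CATEGORY = "IV"


@dataclass(frozen=True)
class IntegrationCall:
    """One gene's joint accessibility x H3K56ac category with its evidence."""

    gene_id: str
    category: str
    atac_evidence: DifferentialRegion | None = None
    cutrun_evidence: tuple[SignalBlock, ...] = ()
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def integrate_at_tss(
    atac_diff: Sequence[tuple[DifferentialRegion, str]],
    unique_treated: PeakSet,
    unique_control: PeakSet,
    genes: Sequence[GeneModel],
    thresholds: DifferentialThresholds = DifferentialThresholds(),
) -> list[IntegrationCall]:
    """Classify every gene by its joint ATAC / H3K56ac state at the TSS.

    ``atac_diff`` must already be TSS-restricted (region, gene_id) pairs;
    when several regions map to one gene the strongest absolute log2 fold
    change provides the gene's accessibility direction.  One call per gene.
    """
    by_gene: dict[str, list[DifferentialRegion]] = {}
    for region, gene_id in atac_diff:
        by_gene.setdefault(gene_id, []).append(region)

    calls: list[IntegrationCall] = []
    for g in genes:
        window = tss_window(g, thresholds.tss_up, thresholds.tss_down)
        gains = tuple(
            p
            for p in unique_treated.peaks
            if overlap_length(p.region, window) > 0
        )
        losses = tuple(
            p
            for p in unique_control.peaks
            if overlap_length(p.region, window) > 0
        )
        regions = by_gene.get(g.gene_id, [])
        directional = [r for r in regions if r.direction != "unchanged"]
        atac = (
            max(directional, key=lambda r: abs(r.log2fc))
            if directional
            else None
        )

        if gains and losses:
            calls.append(
                IntegrationCall(
                    g.gene_id, "uncalled", atac, gains + losses, ambiguous=True
                )
            )
            continue
        if atac is None or (not gains and not losses):
            calls.append(
                IntegrationCall(g.gene_id, "uncalled", atac, gains + losses)
            )
            continue

        opening = atac.direction == "gained-open"
        if opening and gains:
            category = "I"
        elif not opening and losses:
            category = "II"
        elif not opening and gains:
            category = "III"
        else:  # opening and losses
            category = "IV"
        calls.append(
            IntegrationCall(g.gene_id, category, atac, gains or losses)
        )
    return calls


def category_counts(calls: Sequence[IntegrationCall]) -> dict[str, int]:
    """Distinct genes per category (all categories present, possibly 0)."""
    counts = {c: 0 for c in CATEGORIES}
    seen: set[tuple[str, str]] = set()
    for call in calls:
        key = (call.category, call.gene_id)
        if key not in seen:
            seen.add(key)
            counts[call.category] += 1
    return counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_integration(
    path: str | Path, calls: Sequence[IntegrationCall]
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#gene_id\tcategory\tatac_log2fc\tatac_p\tatac_region\t"
            "cutrun_regions\tambiguous\n"
        )
        for c in calls:
            if c.atac_evidence is not None:
                r = c.atac_evidence.region
                lfc = f"{c.atac_evidence.log2fc:.6g}"
                p = f"{c.atac_evidence.p_value:.6g}"
                reg = f"{r.chrom}:{r.start}-{r.end}"
            else:
                lfc = p = reg = "."
            cr = (
                ";".join(
                    f"{b.region.chrom}:{b.region.start}-{b.region.end}"
                    for b in c.cutrun_evidence
                )
                or "."
            )
            fh.write(
                f"{c.gene_id}\t{c.category}\t{lfc}\t{p}\t{reg}\t{cr}\t"
                f"{int(c.ambiguous)}\n"
            )


def write_category_counts(path: str | Path, counts: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("#category\tn_genes\n")
        for cat in CATEGORIES:
            fh.write(f"{cat}\t{counts.get(cat, 0)}\n")
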