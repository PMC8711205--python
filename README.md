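# chromintegrate

A coordinate-only Python toolkit for the joint analysis of chromatin
accessibility (ATAC-seq), histone-mark occupancy (CUT&RUN for H3K56ac) and
linker-histone stoichiometry (RP-HPLC) during drug-induced differentiation
of embryonic stem cells — e.g. mESCs exposed to the HDAC inhibitor
valproic acid.  It is aimed at epigenomics analysts who have already
aligned their reads and want a tested, reproducible implementation of the
downstream decision rules, together with seeded synthetic-data generators
that make every step verifiable against a planted truth.

## What it computes

**Sparse-enrichment peak calling (CUT&RUN).**  From a per-replicate
bedGraph track, maximal runs of strictly positive coverage become signal
blocks scored by total signal, AUC = Σ value × segment length.  Stringent
calling keeps the top ⌈t·N⌉ blocks by AUC (default t = 0.05).
Post-processing follows with: a half-mean filter (drop peaks with
AUC < ½·mean AUC of the file), replicate consensus (keep regions whose
replicate peaks share ≥ 300 bp, emitting the union span), and
condition-unique peaks (consensus peaks with zero overlap against the
other condition's consensus set).

**Differential accessibility (ATAC).**  Per region r with raw counts
k<sub>rs</sub> and library sizes N<sub>s</sub>, the fold change is
FC = (mean treated CPM + c) / (mean control CPM + c), pseudocount
c = 0.5 CPM, and significance comes from a two-sided exact binomial test
on pooled counts: k = Σ treated counts out of n = Σ all counts with
success probability π = Σ treated N / Σ all N (minimum-likelihood
two-sided convention).  A region is *gained-open* when p < 0.001 and
FC > 4, *gained-closed* when p < 0.001 and FC < ¼, else *unchanged*.
Differential regions are restricted to strand-aware TSS windows
(−5000/+3000 bp).

**Annotation.**  Peaks map to the gene whose 10-kb-flanked body they
overlap most (promoter takes precedence over genebody via the TSS
window); differential regions are summarised per transposable-element
class as the percentage of direction-matched, TE-overlapping peaks.

**Integration at TSSs.**  Each gene is classified by its joint state:
category I (gain accessibility ∧ gain H3K56ac), II (lose ∧ lose),
III (lose accessibility ∧ gain H3K56ac), IV (the remaining quadrant,
flagged), or uncalled when either line of evidence is missing or the
H3K56ac evidence is contradictory.

**H1 stoichiometry.**  RP-HPLC A214 peak areas are baseline-corrected,
integrated by trapezoid, divided by each subtype's peptide-bond count,
and expressed per nucleosome via half the adjusted H2B area (two H2B
copies per nucleosome):

    ratio(s) = A_adj(s) / (A_adj(H2B) / 2),   total H1 = Σ_s ratio(s)

## Worked example

Quantify the synthetic control and treated chromatograms and compare the
total H1/nucleosome ratios:

```python
from chromintegrate import SimulationConfig, simulate_chromatogram
from chromintegrate import quantify_sample, percent_change

cfg = SimulationConfig(seed=1)
totals = {}
for cond in ("control", "treated"):
    chrom, windows, subtypes, _ = simulate_chromatogram(cfg, cond)
    res = quantify_sample(chrom, windows, subtypes)
    totals[cond] = res.total_ratio
    print(f"{cond}: total H1/nucleosome = {res.total_ratio:.3f}")
trunc, exact = percent_change(totals["control"], totals["treated"])
print(f"percent change: {trunc} (exact {exact:.2f})")
```

prints

```
control: total H1/nucleosome = 0.580
treated: total H1/nucleosome = 0.670
percent change: 15 (exact 15.59)
```

i.e. the treated culture carries about 0.09 more H1 per nucleosome — a
15% rise — with the small deviation from the generator's planted 0.58 and
0.67 reflecting detector noise in the simulated traces.

The same analysis runs end to end from the shell:

```
chromintegrate simulate --outdir bundle --seed 1
chromintegrate run-all --indir bundle --outdir out --seed 1
```

which emits per-stage TSVs (peak sets, differential calls, annotations,
integration categories, H1 ratios) plus `run_log.json` recording every
parameter, library version and input checksum.  On the default synthetic
bundle the integration summary recovers the planted category structure
(11 gain/gain, 73 lose/lose, 5 lose/gain genes, minus occasional losses
to coverage noise).

Subcommands `callpeaks`, `consensus`, `unique`, `atac-diff`, `annotate`,
`integrate` and `h1quant` expose the individual stages.

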