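# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `chromintegrate`.  The package operates purely on
coordinates and summary signals: read alignment, upstream peak calling of
ATAC fragments, count-matrix construction and motif/ontology analyses are
out of scope.

## Coordinate conventions

All intervals are 0-based, half-open (BED convention); bedGraph and BED
I/O use it natively, and any 1-based upstream annotation must be converted
at the reader boundary.  The TSS of a plus-strand gene is `body.start`; on
the minus strand it is `body.end - 1` (the last base of the body).
Nearest-base conventions for minus-strand TSSs differ by ±1 between tools;
this package fixes the choice above and mirrors TSS windows so that
"upstream" is always 5′: `[tss-up, tss+down)` on the plus strand,
`[tss-down+1, tss+up+1)` on the minus strand, clipped at the origin.
Gene-body flanks are strand-independent.

Replicate reproducibility is interpreted as *overlap* of at least 300 bp
between replicate peaks, not as a centre-to-centre distance; the two
readings differ, and the overlap reading matches the way the consensus
step is parameterised ("region overlap … minimum of 300 bp").

## Sparse-enrichment peak calling

Candidate peaks are maximal runs of strictly positive bedGraph signal;
each carries its total signal (AUC = Σ value × segment length) and its
maximum value.  Input records must be coordinate-sorted, chromosome-
contiguous and non-overlapping; violations raise a format error rather
than being silently reordered.

* **Stringent calling** keeps the top `ceil(threshold × N)` blocks by
  AUC (`threshold` = 0.05 by default).  Ties on AUC break by
  (chrom, start); the ceiling guarantees a non-empty result whenever any
  block exists.
* **Half-mean filter**: peaks with AUC below half the mean AUC of the
  file are dropped.  The mean is computed once over the input set, not
  iterated to a fixed point, and "signal value" is read as the peak's
  total signal (its primary score); the maximum-value reading is a
  plausible alternative that is not implemented.
* **Replicate consensus**: every replicate pair sharing ≥ `min_overlap`
  (default 300) bp contributes the union span of the pair; spans chained
  through shared peaks merge into one consensus region whose AUC is the
  sum of all distinct contributing blocks.  The union (rather than
  intersection) keeps broad enrichment domains intact for downstream
  gene mapping.
* **Condition-unique peaks** require *zero* overlap against every
  consensus peak of the other condition — the strictest reading; no
  overlap tolerance is applied.

Only the numeric-threshold, stringent configuration is provided; the
IgG/control-track branch and relaxed mode of SEACR-style callers are
deliberately absent.  Fragment-level input is reduced to a single filter
contract: paired-end fragments on one chromosome with length strictly
below 1000 bp are retained.

## Differential accessibility

The DESeq2-style NB regression usually applied to ATAC count matrices is
replaced by a deterministic, oracle-checkable exact test; the decision
layer (raw p < 0.001 AND linear fold change > 4 up or down) is preserved
exactly.  This is a deliberate departure documented here: per region, the
two-sided exact binomial test asks whether the treated share of pooled
raw counts is consistent with the treated share of summed library sizes
(minimum-likelihood two-sided convention, implemented by direct pmf
enumeration and cross-checked in tests against an independent exact-test
routine).  Fold changes use library-size-normalised CPM with a 0.5-CPM
pseudocount on both means; the threshold applies to the pseudocounted
raw ratio (no shrinkage).  No multiple-testing correction enters the
decision rule; a Benjamini–Hochberg FDR column is emitted for reference.

The pooled binomial test is exactly calibrated when counts are
Poisson-distributed across conditions (Poisson splitting).  Under
negative-binomial overdispersion with variance μ(1 + αμ) the test is
anti-conservative: the tail rate at p < 0.001 grows like
2Φ(−3.29/√(1+αμ)).  The synthetic generator therefore defaults to
α = 0.001 (technical-replicate-level variation; variance inflation 1.05
at the default depth of 50 counts/region/sample).  **Limitation:** with
biologically dispersed replicates (αμ ≳ 0.1) the raw p-values are too
small and a dispersion-aware model should replace the exact test.

## Annotation

A peak is assigned to the gene whose flank-extended body (default
10 kb each side) it overlaps most; ties break by smallest gene start,
then gene id.  Assigned peaks are `promoter` when they touch the TSS
window (the ATAC window, −5000/+3000, reused as the promoter definition —
an assumption, since no separate promoter window is defined upstream),
else `genebody`; unassigned peaks are `intergenic`.  TE-overlap summaries
report, per direction and TE class, 100 × (direction-matched peaks
overlapping ≥ 1 element of the class) / (direction-matched TE-overlapped
peaks); a peak spanning several classes counts once per class, so
percentages within a direction may sum above 100.  A switch substitutes
all direction-matched peaks as the denominator for the alternative
normalisation.

## Integration at TSSs

Evidence is presence-based, not quantitative: a treated-unique consensus
peak overlapping a gene's TSS window is an H3K56ac gain, a control-unique
peak a loss.  The gene's accessibility direction comes from its
TSS-restricted differential regions (strongest |log2FC| wins when several
map to one gene).  Joint states map to categories I (gain, gain),
II (lose, lose), III (lose, gain) and IV (gain, lose); IV completes the
2×2 logic and is flagged as the extra quadrant rather than dropped.
Genes with contradictory H3K56ac evidence (both a gain and a loss peak
over the window) are flagged ambiguous and left uncalled.  Co-occurrence
within the same TSS window suffices; the CUT&RUN peak and the ATAC region
are not required to overlap each other.

## H1/nucleosome stoichiometry

Peak areas are integrated by trapezoid after subtracting a linear
baseline drawn between the signal values at the window bounds.  Each
bound's signal value is estimated as the local mean within ±0.05 min
(configurable; 0 recovers the raw single-sample anchor): anchoring on a
single sample propagates detector noise into the area with standard
deviation ≈ window width × σ_noise, which for a minor subtype like H1⁰
(molar amount ~0.01 relative to H2B) can exceed the peak area itself.
A `baseline="none"` option integrates the raw trace.  Negative areas are
clipped to zero with a warning.

Because A214 absorbance scales with peptide-bond count, areas are divided
by (residues − 1) per subtype before molar comparison; the bond table is
a configuration input (a default mouse table ships with the synthetic
generator).  Whether the adjustment divides by the bond count or rescales
by a bond-count ratio to a reference is immaterial: the constant cancels
in every ratio.  The nucleosome reference is half the adjusted H2B area
(two H2B copies per nucleosome).  Percent changes are reported both exact
and truncated toward zero to integer percent.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
with truth manifests sufficient to match every planted entity by
coordinates alone.  Every generator is a pure function of the
configuration; sub-streams are derived from the master seed by fixed
offsets so adding a generator never perturbs existing outputs.

* **Genome/annotation** — default 2 chromosomes × 2 Mb with 200 genes on
  a slot grid whose margins guarantee non-overlapping TSS windows, plus
  400 TEs of classes LTR/SINE/LINE/DNA.  Problem sizes were chosen so a
  full run completes in well under a minute.
* **CUT&RUN tracks** — per-bin (10 bp) Poisson background at rate 0.5,
  with planted 800-bp blocks at rate × enrichment_fold (default 10);
  when the background rate is zero the planted rate equals the fold
  itself so blocks remain the only signal.  With these defaults
  background runs of positive bins are geometrically short (≈ 16 bp on
  average, essentially never ≥ 300 bp), so the replicate-consensus step
  suppresses background while planted blocks stay contiguous.  Category
  I/III genes receive treated-unique blocks over the TSS, category II
  genes control-unique blocks, and shared blocks land away from all TSS
  windows.  Replicates share block positions and differ only in noise.
  Planted blocks occasionally fragment at Poisson-zero bins, which can
  cost a block the 300-bp consensus; measured pooled over 20 simulations
  the chain recovers ≈ 98% of planted blocks with ≈ 0 false discovery.
* **ATAC counts** — NB counts (mean 50, α = 0.001) over 2000 regions;
  category-gene regions sit over the TSS with the planted direction, 100
  further planted regions (half open, half closed, kept out of category
  TSS windows so they cannot override a planted direction) and unchanged
  background regions fill a slot grid.  Planted fold changes default to
  8; library sizes are column sums.
* **Chromatograms** — sums of Gaussians (σ = 0.15 min, centres ≥ 4σ
  apart) whose areas equal amount × peptide bonds, so bond-adjusted areas
  recover molar amounts exactly; plus a linear baseline (1% drift) and
  additive Gaussian noise at 3 × 10⁻⁴ of the tallest peak height
  (≈ 0.1 mAU — realistic detector noise).  Control amounts sum to 0.29
  of H2B, treated to 0.335, so the planted total ratios are 0.58 and
  0.67 with the subtype pattern (H1a/H1b/H1e/H1⁰ up, H1d down, H1c flat)
  characteristic of HDACi-treated mESCs.
* **Integration inputs** — a noise-free constructor emits TSS-restricted
  differential records and condition-unique peak sets directly from the
  planted categories (default {I: 11, II: 73, III: 5}) for deterministic
  classification checks.

What passing these tests shows — and does not.  The generators exercise
the decision rules under clean, well-separated conditions: planted
effects are large (8-fold), replicates are technical-grade, enriched
blocks are rectangular, and chromatogram peaks are ideal Gaussians in
non-overlapping windows.  Real data add biological replicate dispersion,
irregular peak shapes, co-eluting HPLC fractions (e.g. H1d/H1e, which the
generator deliberately separates), and mappability artefacts; recovery
rates measured here are upper bounds on real-data performance.

## Pipeline and reproducibility

`run_pipeline` executes peak calling → differential → annotation →
integration → H1 quantification; stages without inputs are skipped and
downstream results degrade explicitly (no CUT&RUN input ⇒ every gene
uncalled).  All outputs are tab-separated with one `#`-prefixed header
line.  `run_log.json` records package and library versions, the seed,
every parameter and SHA-256 checksums of all inputs; two runs on the same
inputs with the same configuration are byte-identical (the output
directory path is excluded from the log for this reason).
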