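# Methods

This note documents the statistical model, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and
the numerical/design choices made where the design was genuinely open.

## Heteroplasmy calling

### Error model and test

Alternate-supporting reads at a site are modelled, under the global null of
no variants, as independent sequencing/PCR errors arriving at per-base rate
*e* = 0.01 (a conservative figure for quality-20-filtered short-read data).
For a site of effective depth *d*, the alternate count is X ~ Poisson(λ =
*e·d*) and the reported p-value is the upper tail P(X ≥ alt_count),
computed through the Poisson survival function (stable for λ up to 10⁴ and
beyond; no explicit log-space summation is needed). The same rate *e* is
applied to each alternate allele separately, which is conservative by up to
a factor of three relative to splitting *e* across the three non-reference
bases.

P-values are adjusted per sample with the Benjamini–Hochberg step-up
procedure over all tested alternate alleles of that sample; the family is
per-sample, not pooled across samples, because the test asks "does this
sample carry variants" and family sizes differ strongly between samples.
Calls are emitted at q ≤ 0.05.

### Filter chain

Gates applied before testing, all configurable in `CallerConfig`:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 1000 reads | sites below this effective depth are not considered |
| `min_aaf` | 0.01 | alternate allele frequency floor (alt / effective depth) |
| `strand_ratio_low/high` | 0.1 / 0.9 (exclusive) | allowed plus-strand fraction of the alternate allele |
| `error_rate` | 0.01 | Poisson null rate per base |
| `fdr_alpha` | 0.05 | BH significance threshold |
| `fixed_variant_aaf` | 0.8 | calls at or above this AAF are fixed variants, not heteroplasmies |

The AAF denominator is the effective depth (all quality-passing reads),
not ref+alt only; "one percent or higher occurrence" is therefore read as
alt/depth. The strand gate is applied to the alternate allele's own strand
split (the standard strand-bias diagnostic); a site simulated with a 5%
plus-strand fraction is rejected by it. Bounds are exclusive. When several
alleles at one site pass, the maximal-AAF allele is reported (ties broken
by count, then alphabetically).

The fixed-variant band at ≥80% AAF reflects the conventional description of
a sample's major sequence differing from the reference (80–100% AAF);
heteroplasmies live strictly below it.

A caveat worth stating: "tightening any threshold never decreases
stringency" is enforced by construction for the gates, but because the BH
family consists of the gated tests, removing a *large*-p hypothesis via a
stricter depth gate can in principle lower the q-values of the remaining
tests. This knife-edge requires borderline q ≈ α configurations that do
not arise in realistic data (null alleles passing the 1% gate sit near
p ≈ 0.5; true signals sit at p ≪ 10⁻⁶), and the randomised monotonicity
property test passes at the study's operating conditions.

### Homopolymer depth accounting

Runs of ≥5 identical bases (the threshold is configurable; the protocols
this follows leave "run" undefined) are sequencing-error hotspots. At sites
within a run or within one flanking position of it (width configurable),
counts and depth are replaced by the subset from reads traversing the
entire repeat; raw counts are retained alongside (`raw_*` columns) so the
strand split before and after adjustment is auditable. A flagged site
without traversing-read counts is a hard error when adjusting — and if the
adjustment step is skipped entirely, the caller refuses to emit flagged
sites, recording `homopolymer_unresolved` in the audit output instead.

### Informative positions

A position is *informative* when the presence of an emitted call differs
between any two strain × treatment × time groups (equivalently: some but
not all groups contain a carrier). An expected full-factorial cell with no
samples is an error.

## Consequence annotation

Gene assignment is by interval containment on the circular reference
(intervals may wrap the origin; wrapping intervals are stored start > end).
For protein-coding genes the affected codon is extracted strand-aware and
wrap-aware from the frame offset, and both codons are translated with the
vertebrate mitochondrial code (AGA/AGG stop, ATA Met, TGA Trp — Biopython
translation table 2). Positions in multiple genes yield one consequence per
gene, protein-coding first; positions outside every annotated gene fall
back to `D-loop/noncoding` rather than erroring, since the mitochondrial
control region is usually left unannotated in minimal interval files.

## qPCR damage assays

Relative amplification is (mean sample − background) / (mean control −
background), with background the mean no-template fluorescence; replicate
CVs are reported. The 50% control must land at 0.5 ± 0.15 of the control
signal or a QC warning is raised. Lesion frequency uses the long-amplicon
Poisson zero-class formula lesions = −ln(rel_amp) × N/amplicon_bp — the
formula is the standard one for this assay family; N = 10,000 bp for the
mitochondrial fragment and 6,500 bp for the nuclear fragment, matching the
units lesions/10 kb and lesions/6.5 kb. Relative amplifications slightly
above 1 (≤ 1.05) are clipped to 1 with a warning (undamaged-sample
variability); larger values are errors. Copy number is calibration_factor ×
the control-normalised short-amplicon signal; the calibration factor
(copies represented by the undamaged control) is an explicit input because
absolute calibration is instrument- and standard-specific. Copy estimates
are invariant to global fluorescence rescaling.

## Synthetic-data generator

The generator realises the conditions the pipeline targets, and its
defaults are fixed accordingly:

- reference: 16,569 bp circular sequence (configurable; the mouse
  mitochondrial genome is ~16.3 kb), 13 non-overlapping protein-coding
  gene intervals, implanted homopolymer runs placed away from gene
  boundaries so consequence tests are unambiguous;
- depth: per-site Poisson with mean 2000× (comfortably above the 1000×
  gate), a simulator convention — the real depth distribution of
  amplicon-sequenced mtDNA is not modelled;
- errors: independent per read at rate 0.01, substituting uniformly over
  the three non-reference bases (the error spectrum is a convention; real
  errors are context-biased);
- heteroplasmies implanted at 1–30% AAF via binomial sampling; fixed
  variants at 99% AAF; strand split binomial at 0.5 unless a per-site
  plus fraction is injected; traversing reads thinned at probability 0.85
  in homopolymer context;
- qPCR: signal = (background + amplitude) × lognormal noise with mean 1
  and CV `noise_cv` (default 0.1 in cohorts; exactly 1 at CV 0, which
  makes noise-free plates invert the estimators exactly — the round-trip
  tests exploit this);
- cohorts: 2 strains × 2 treatments × 2 times × n = 4, with group-level
  heteroplasmy profiles at 1–30% AAF (shared and group-private sites, a
  strain-private fixed variant) and damage truth exhibiting a
  strain-by-treatment copy-number deficit and a late mitochondrial lesion
  burden, with flat nuclear lesions.

What passing tests on this generator shows: the caller's gates, test and
FDR control behave correctly for count data with the assumed error
structure, and the damage estimators exactly invert their forward model.
What it does not show: robustness to alignment artifacts, indels, PCR
duplicates, context-dependent error spectra, NUMT contamination, or
amplification-curve pathologies — read-level simulation and alignment are
out of scope by design.

## Numerical and interface choices

- Coordinates are 1-based inclusive everywhere; variants are named
  `<ref><position><alt>` (e.g. T9461C).
- BH adjustment delegates to statsmodels' `fdr_bh`; the test suite checks
  it against an independent step-up implementation on vectors up to 50,000.
- The ANOVA is OLS with Type-II sums of squares (invariant to main-effect
  ordering, sensible for the mildly unbalanced n = 3–4 cells; identical to
  Type I on balanced data, which the tests verify). Tukey HSD uses the
  studentized range; at k = 2 it reduces to the pooled t-test.
- "Combined heteroplasmy frequency" for a group-site is the mean AAF over
  the group's carrier samples by default; a `sum` convention is available
  because group-level summaries in the wild are not always attributable to
  one convention. Per-group mean percent heteroplasmy averages over loci
  within a sample first, then over samples; call-free samples contribute
  0%, which keeps group means well-defined in low-heteroplasmy groups.
- Degenerate inputs are explicit: empty pileup with a valid header parses
  to an empty table; empty group-site tables yield zero-count descriptives
  with NaN extremes; a factor with one level, a singleton Tukey group, a
  zero-sample design cell, and a control at background are all named
  errors.
- Simulation sizes in the test suite (e.g. 200 null seeds at 16,569 sites;
  1000 ANOVA replicates) were chosen to give Monte-Carlo standard errors
  small enough for the stated acceptance bands while keeping the default
  test run in the tens of seconds.

## Known limitations

- No indels, multi-nucleotide variants, NUMT filtering or haplogroup
  logic; the caller is SNV-only.
- The quality policy is carried as metadata; per-base quality filtering
  happens upstream when pileups are produced from alignments (alignment
  itself is out of scope), so raising the floor on an already-built table
  is a no-op rather than a recount.
- qPCR modelling is endpoint-fluorescence only: no Cq/threshold-cycle or
  amplification-curve fitting.
- Heteroplasmy–copy-number correlation analyses are deliberately absent;
  at n = 3–4 per cell they are not meaningful.
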