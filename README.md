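# mthet

Low-frequency mitochondrial heteroplasmy calling, consequence annotation,
and qPCR-based mtDNA damage quantification — with a first-class synthetic
cohort generator so the whole pipeline is testable end to end without any
external data.

## Who this is for

Groups doing ultra-deep mitochondrial genome sequencing in small animal
cohorts (strain × exposure × time designs) who want to (i) call
heteroplasmies — alternate alleles segregating at 1–30% frequency across a
sample's mtDNA copies — against a sequencing-error null, (ii) classify
calls as synonymous/nonsynonymous under the vertebrate mitochondrial code,
(iii) summarise heteroplasmy at the group level, and (iv) quantify mtDNA
lesions and copy number from long-amplicon qPCR plates.

## The model

**Heteroplasmy caller.** For each sample, at each position of a circular
mitochondrial reference, reads are counted per allele per strand (minimum
base and alignment quality 20). A candidate alternate allele at a site is
tested only if

- effective depth ≥ 1000× (at sites within or adjacent to a homopolymer
  run, only reads traversing the entire repeat are counted),
- alternate allele frequency AAF = alt/depth ≥ 1%,
- the allele's plus-strand fraction lies strictly inside (0.1, 0.9).

Under the global null that all alternate reads are PCR/sequencing errors,
the alternate read count is X ~ Poisson(λ = e·depth) with per-base error
rate e = 0.01, and the site's p-value is P(X ≥ alt_count). P-values are
Benjamini–Hochberg adjusted across all tested alleles of the sample
(families can reach ~50,000 tests) and calls are emitted at q ≤ 0.05.
Emitted calls with AAF ≥ 80% are classified as *fixed variants* — the
sample's major sequence differing from the reference — rather than
heteroplasmies. Note the AAF gate alone can never clear the test: a 1%
allele at 1000× sits at the centre of the null (p > 0.5).

**Damage assays.** Polymerase-blocking lesions suppress amplification of a
long amplicon. With lesion counts Poisson-distributed along the template,
only the zero class amplifies, so

    lesions per N bp = −ln(A_damaged / A_control) × N / amplicon_bp

with the mitochondrial fragment (10 kb) normalised per 10 kb and the
nuclear β-pol fragment per 6.5 kb. A short mitochondrial amplicon is
insensitive to lesions at these rates; its background-subtracted,
control-normalised signal is linear in mtDNA copy number (scaled by an
explicit calibration factor). Plates carry 100% and 50% undamaged controls
(the latter validates the quantitative range) and no-template background
wells.

**Group statistics.** Per-site group "combined heteroplasmy frequency"
(mean AAF over carrier samples; a sum convention is switchable), per-group
mean percent heteroplasmy (per-sample mean over heteroplasmic loci, 0% for
call-free samples, then mean ± SE over samples), and a fixed-effects
2×2×2 factorial ANOVA (Type-II sums of squares) with Tukey HSD post hoc.

## Worked example

```python
import mthet as m

ref = m.generate_reference(length=16_569, n_genes=13, seed=7)
truth = m.TruthSet(
    "mouse1",
    heteroplasmies=[(9461, ref.base_at(9461), "C", 0.26)],
    lesion_rate_mt=2.82, lesion_rate_nuc=0.3, copy_number=7064,
)
pile = m.simulate_pileup(ref, truth, mean_depth=2000, error_rate=0.01, seed=1)
calls = m.annotate_table(m.call_sites(m.homopolymer_adjusted_depth(pile, ref)), ref)
print(calls[["position", "variant", "aaf", "q_value", "status", "gene_name"]])

plate = m.simulate_qpcr_plate(truth, noise_cv=0.0, seed=0)
print(m.analyze_plate(plate, calibration_factor=10_000.0))
```

prints

```
 position variant      aaf  q_value       status gene_name
     9461  C9461A 0.255665      0.0 heteroplasmy synGene08
  compartment  rel_amp  lesions_per_norm  copies_per_input
mitochondrial 0.059606              2.82               NaN
      nuclear 0.740818              0.30               NaN
  copy_number 0.706400               NaN            7064.0
```

The implanted 26%-AAF heteroplasmy is recovered at 25.6% (within binomial
sampling error at ~2000× depth) and emitted at q ≈ 0; the noise-free qPCR
plate inverts exactly to the programmed 2.82 lesions/10 kb, 0.30 nuclear
lesions/6.5 kb, and 7064 mtDNA copies per input.

A command-line workflow covers the same ground on a full synthetic cohort
(2 strains × 2 treatments × 2 time points × 4 samples):

```bash
mthet all --seed 42 --force            # simulate → call → summarize → damage
mthet summarize --table src/mthet/data/table1_fixture.tsv
# {"n_sites": 13, "n_nonsynonymous": 4, "min_frequency_pct": 1.1, "max_frequency_pct": 26.0}
```

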