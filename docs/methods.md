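# Methods

## Model and procedure

`kinpile` estimates pairwise relatedness between individuals observed as
pseudo-haploid genotypes: one sequencing-read allele per SNP, the
standard representation when coverage is far below 1× and diploid calls
are impossible. The pipeline has three stages.

**1. Pseudo-haploid calling.** From samtools-mpileup text restricted to
the panel positions, bases below a Phred quality floor
(`min_base_quality`, default 30 — a conventional ancient-DNA choice;
the value affects only which reads survive, not the estimator) or not
matching either panel allele are discarded, and one surviving base is
drawn uniformly at random. Triallelic or damaged bases therefore reduce
depth rather than invalidating the site, which maximizes usable loci at
ultra-low coverage. PLINK text input (.ped/.map, .tped/.tfam) bypasses
calling; diploid heterozygotes are pseudo-haploidized by a seeded random
allele draw so that all downstream expectations stay on the halved
scale.

**2. Pairwise intersection.** For each pair, the loci non-missing in
both individuals are intersected with the panel and each carried
allele's population frequency attached (allele2 carriers get
`1 − freq1`). Panels must contain only non-fixed biallelic SNPs; fixed
and non-ACGT loci are filtered at load. No minor-allele-frequency or
linkage-disequilibrium pruning is applied — rare variants carry most of
the estimator's information and pruning would only shrink the usable
locus count.

**3. Estimation and classification.** The Queller–Goodnight estimator
is evaluated in both directions at every locus (pseudo-haploid
reduction `(I − p)/(1 − p)`; the general four-allele form is retained
for diploid input and as the test oracle) and the symmetric per-locus
values are averaged across loci (`mean_of_ratios`, the default). A
SPAGeDI-style multilocus variant (`ratio_of_sums`: accumulate
numerators and denominators per direction, average the two ratios) is
provided behind a flag; the two coincide when all carried alleles share
one frequency and differ only at second order otherwise. Classification
uses hard thresholds at the class mid-points (0.0625, 0.1875), with
boundary values assigned upward (conservative for relative-exclusion
workflows) and the [0.0625, 0.090) band labelled
`second_or_third_degree`; the 0.090 edge is configurable. Estimates are
never suppressed at low SNP counts — pairs with < 4,000 shared SNPs are
reported with the `below_threshold` tier rather than dropped, since
usable 1st-degree signals exist well below that count.

## Simulation engine

Simulated pairs follow an IBD-copy model: x draws allele1 with
probability `freq1`; with probability *k*, y copies x's allele,
otherwise y draws independently. Conditional on no copy the per-locus
estimator has expectation 0, and on copy exactly 1, so the multilocus
expectation equals *k* for **any** non-fixed frequency spectrum — this
is why class means 0 / 0.125 / 0.25 are recovered without calibration
constants. Per SNP count, every simulated pair draws a fresh random
locus subset, so distribution widths reflect both genotype and locus
sampling, matching real pairs, which overlap different loci. Per-class
normal fits supply posterior probabilities (equal priors by default,
configurable; a kernel-density fit is available behind a flag), and
false-positive rates are the fractions of each class's samples outside
its own hard-threshold band. When a real pair's SNP count is not a
simulated grid point the nearest count is used and logged (default grid
1,000–30,000).

## Synthetic data

The fixture generator emulates a genome-wide panel of non-fixed
biallelic SNPs with frequencies truncated to [0.001, 0.999]. The
default spectrum is **uniform**: its per-locus estimator variance puts
the unrelated-class spread at ~0.07 HRC for 1,000-SNP pairs, shrinking
to ~0.02 at 20,000, which reproduces the false-positive-rate scale
observed with real genome-wide population panels (roughly 35–50% of
2nd-degree pairs crossing a threshold at 1,000 SNPs, falling below 1%
by 15,000). A symmetric beta option (default α = β = 0.5) provides a
heavier-tailed, drift-like spectrum; more extreme shape parameters
(e.g. α = β = 0.2) pile so much mass at the truncation bounds that
per-locus variances exceed real-panel behaviour by an order of
magnitude, so they are useful only as worst-case stress inputs.
Cohorts are generated under the same IBD-copy model with known truth;
synthetic pileups use Poisson depths (or a constant depth), a uniform
per-read error to one of the three other bases, and constant base
qualities. Not modelled: post-mortem deamination damage, reference
bias, strand flips (panels and reads are assumed on one reference
strand), background relatedness inside the reference panel, and linkage
between loci. Passing tests on synthetic data therefore demonstrate the
statistical machinery, not robustness to damage-driven artefacts —
on real data those are mitigated upstream (damage rescaling, transversion
panels) or by the known-unrelated normalization.

## Normalization for mismatched panels

When panel ancestry and sample ancestry diverge, all HRC estimates
shift upward roughly in parallel. `normalize_unrelated` subtracts the
mean HRC of user-designated known-unrelated pairs and re-classifies;
subtraction (rather than rescaling) is used because the shift is
additive in the per-locus expectation under frequency misspecification,
and it restores published mismatched-panel estimates to their expected
ranges (e.g. a 1st-degree mean of 0.3131 over an unrelated baseline of
0.1149 corrects to 0.1982). The uncorrected value is kept alongside.

## Numerical and design choices

- Frequencies are kept strictly inside (0,1); the per-locus denominator
  `1 − p` can therefore never vanish on the pseudo-haploid path. The
  general four-allele form can hit a zero denominator only with
  boundary frequencies, which the panel loader excludes.
- All randomness flows through `numpy.random.default_rng`;
  seed-sequence spawning gives independent, reproducible streams per
  individual / SNP count / class. Reports are byte-identical across
  reruns of the same configuration and independent of `--threads`
  (pair-level estimation is RNG-free).
- Panel positions come from an optional POS column or from `chrom_pos`
  SNP ids; panels without either still support the PLINK (id-matched)
  path.
- Problem sizes in the test and acceptance workloads — 500 pairs per
  class at 20,000 loci for class-mean recovery; 2,000 pairs per SNP
  count for the false-positive-rate curve — put Monte-Carlo standard
  errors (~0.002 HRC on class means) an order of magnitude below the
  ±0.01 bands they are checked against.

## Limitations

- Degrees beyond 2nd are not assessed; 3rd-degree pairs surface only
  via the cautionary 0.0625–0.090 band. Parent–offspring vs sibling
  disambiguation and inbreeding are out of scope.
- Posteriors assume the three canonical classes and the panel's
  frequencies; with a badly mismatched panel they should be read only
  after normalization.
- The BAM wrapper shells out to `samtools mpileup`; alignment, duplicate
  removal and damage rescaling are upstream of this package.
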