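# kinpile

Pairwise kinship classification for ultra-low-coverage ancient DNA.

Ancient-DNA screening routinely produces genomes at 0.01–0.1× coverage —
far too sparse for diploid genotype calls, but enough to ask whether two
skeletons from the same site were close relatives. `kinpile` answers that
question from **pseudo-haploid** data: at every SNP covered by at least
one read, a single read is sampled at random and its allele becomes the
individual's genotype. Pairwise relatedness is then estimated against a
population allele-frequency panel and classified as unrelated,
2nd-degree (grandparent–grandchild, half-siblings, avuncular) or
1st-degree (parent–offspring, full siblings).

## The estimator

For individuals *x* (alleles *a*, *b*) and *y* (alleles *c*, *d*) at one
locus, with population allele frequencies *p*, the Queller–Goodnight
relatedness estimator is

```
r_xy,l = (0.5·(I_ac + I_ad + I_bc + I_bd) − p_a − p_b) / (1 + I_ab − p_a − p_b)
```

where the *I* are allele-identity indicators. The per-locus value is
direction-dependent; `kinpile` averages r_xy and r_yx per locus and then
across all loci shared by the pair. On pseudo-haploid data (*a* = *b*,
*c* = *d*) the formula reduces to `(I − p_a)/(1 − p_a)` and the expected
coefficient is **half** its diploid value — a *halved relatedness
coefficient* (HRC): 0.25 for 1st-degree pairs, 0.125 for 2nd-degree,
0 for unrelated. Hard classification thresholds sit at the class
mid-points, **0.1875** and **0.0625**; estimates in [0.0625, ~0.090)
are reported as "2nd- or 3rd-degree" because 3rd-degree pairs
(expected HRC 0.0625) overlap that band.

Because class distributions widen as the SNP count shrinks, a
Monte-Carlo engine simulates pairs of each class at any SNP count from
the panel frequencies, yielding per-count false-positive rates and
posterior class probabilities for borderline estimates, plus
SNP-count confidence tiers (≥18,000 shared SNPs: high; ≥11,000:
medium; ≥4,000: low — 1st-degree pairs still detectable as related).
For panels that poorly match the test population's ancestry, estimates
can be re-centred by subtracting the mean HRC of known-unrelated pairs.

## Worked example

Generate a synthetic cohort with known truth (a 1st-degree pair
`anc1`/`anc2`, a 2nd-degree pair `anc3`/`anc4`, an unrelated `anc5`) as
single-read-depth pileups over a 20,000-SNP panel, then run the
pipeline:

```sh
kinpile fixtures --loci 20000 --pairs "anc1,anc2,0.25;anc3,anc4,0.125" \
    --singles anc5 --seed 11 --out-dir demo
kinpile relate --panel demo/panel.frq \
    --pileup demo/anc1.pileup --pileup demo/anc2.pileup \
    --pileup demo/anc3.pileup --pileup demo/anc4.pileup \
    --pileup demo/anc5.pileup --out-dir demo/run --seed 11
```

`demo/run/relatedness_report.tsv` (columns abridged):

```
id_x   id_y   n_snps  hrc        class_label    confidence_tier
anc1   anc2   8009    0.302624   first_degree   low
anc3   anc4   7936    0.151016   second_degree  low
anc2   anc3   7873    0.060910   unrelated      low
anc1   anc3   7983    0.038621   unrelated      low
...
anc3   anc5   7986    -0.025007  unrelated      low
```

At Poisson depth 1 each individual covers ~63% of the panel, so pairs
overlap at ~8,000 SNPs; both true related pairs land in their correct
class and all cross-pairs are unrelated. The `low` tier flags that with
fewer than 11,000 SNPs a borderline call deserves posterior support:

```sh
kinpile simulate --freq demo/panel.frq --pairs 500 \
    --snp-counts 5000,8000,10000 --seed 11 --out demo/dist.tsv
kinpile posterior --dist demo/dist.tsv --hrc 0.1510 --snps 7936
```

```
second_degree   0.996
first_degree    0.004
unrelated       0.000
```

i.e. the 0.1510 estimate for `anc3`/`anc4` is 2nd-degree with posterior
probability 0.996 under equal class priors.

Real data enter the same way: `samtools mpileup` text restricted to the
panel positions (one file per individual; the
`kinpile.pileup.bam_to_pileup` helper wraps the samtools call), or
existing PLINK .ped/.map / .tped/.tfam genotypes via `--plink`, which
skips the calling stage. The panel is a PLINK `.frq`-dialect file of
non-fixed biallelic SNPs with the frequency of allele A1.

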