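# exonpop

Downstream analysis of multi-population exome variant call sets, in the
style of the deep exon-capture pilot studies: two calling pipelines' site
filters and their intersection QC, codon-level functional annotation,
nucleotide diversity and allele-frequency spectra, cross-population
minor-allele sharing, allele-frequency-binned functional enrichment with
error-rate correction, and validation-assay arithmetic. A synthetic
multi-population cohort generator with known ground truth makes every stage
testable without access to raw study data.

It is written for population geneticists and variant-calling method
developers who want the *analysis* half of an exome study — everything after
the genotype matrix — as reusable, tested building blocks that run on real
VCFs or on simulated cohorts.

## The statistics at its core

* **Pairwise heterozygosity.** A site with allele count *j* among *n*
  chromosomes contributes 2*j*(*n*−*j*)/(*n*(*n*−1)), the fraction of
  chromosome pairs differing there; per-base diversity divides the summed
  heterozygosity of a site class (missense, two-/three-/four-fold
  degenerate) by the number of *callable* bases of that class (≥10× depth in
  ≥100 chromosomes).
* **Allele-frequency spectra.** Unfolded spectra count derived alleles
  (polarized by an outgroup base), folded spectra minor alleles. Sites
  observed at heterogeneous chromosome counts are projected to a common size
  *m* with the hypergeometric expectation
  E[count *i* | *j* of *n*] = C(*j*,*i*)·C(*n*−*j*, *m*−*i*)/C(*n*,*m*);
  Watterson's θ<sub>W</sub> = S/a<sub>n−1</sub> and the constant-size
  neutral expectation θ/*i* provide the null.
* **Minor-allele sharing.** The probability that two minor alleles, drawn at
  random without replacement, come from the same population, different
  populations on one continent, or different continents — exact
  combinatorics of the per-population minor counts, compared against the
  panmictic expectation (the same formula on sample sizes, independent of
  frequency), with hypergeometric down-sampling to equalize panels and
  bootstrap CIs over sites.
* **Filters and QC.** Quality-based filtering (site quality ≥40 plus one
  confident carrier), artifact-signature filtering (QD ≥5; adjacent
  allele-sharing homopolymer run ≤3; mean reference allele balance over
  heterozygotes <0.75; no cluster of ≥3 variants within 10 bases), call-set
  intersection keyed by (chrom, pos, ref, alt), Ts/Tv and %known summaries,
  5-bp indel equivalence merging, and the length-1-singleton /
  two-variant-read indel rules.
* **Enrichment and validation arithmetic.** Minor-AF bins (<0.01, 0.01–0.1,
  >0.1), per-bin error-rate deflation c′ = c·(1−e<sub>b</sub>), chi-square
  class contrasts, and the contingency arithmetic of validation rates and
  3×3 called-vs-assayed genotype accuracy tables.

## Worked example

Simulate a six-population cohort (two populations per continent, 60 samples
each) with a rare-allele skew on amino-acid-changing classes, then ask the
two headline questions — are functional variants enriched at low frequency,
and are rare alleles population-specific?

```python
import exonpop as ep

cfg = ep.SimulationConfig(
    populations=(ep.PopulationSpec("YRI", "Africa", 60),
                 ep.PopulationSpec("LWK", "Africa", 60),
                 ep.PopulationSpec("CHB", "Asia", 60),
                 ep.PopulationSpec("JPT", "Asia", 60),
                 ep.PopulationSpec("CEU", "Europe", 60),
                 ep.PopulationSpec("TSI", "Europe", 60)),
    n_sites={"silent": 1500, "missense": 1800, "nonsense": 100},
    selected_classes=("missense", "nonsense"), selection_skew=0.4,
    fst=0.08, seed=42)
cohort = ep.simulate_cohort(cfg)

binned = ep.bin_by_af(cohort.sites, error_rates=(0.062, 0.032, 0.034))
r = ep.class_contrast(binned, "silent", "missense")
print(f"sub-1% fraction: silent {r.low_fraction_a:.2f}, "
      f"missense {r.low_fraction_b:.2f}")
print(f"chi2 = {r.statistic:.1f} (df {r.df}), p = {r.pvalue:.3g}")

spec = ep.DownsampleSpec(m={p: 120 for p in cohort.panel.populations})
est = ep.downsampled_sharing(cohort.sites, spec, cohort.panel,
                             bootstrap_reps=500, seed=1)
print(est.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("panmictic expectation:",
      tuple(round(x, 3) for x in ep.panmictic_expectation(spec.m, cohort.panel)))
```

prints

```
sub-1% fraction: silent 0.17, missense 0.22
chi2 = 54.2 (df 2), p = 1.68e-12
     bin             category  estimate  ci_low  ci_high  n_sites
   <0.01      same_population     0.665   0.635    0.694      542
   <0.01       same_continent     0.188   0.165    0.214      542
   <0.01 different_continents     0.147   0.124    0.170      542
0.01-0.1      same_population     0.419   0.408    0.429     1449
0.01-0.1       same_continent     0.220   0.213    0.228     1449
0.01-0.1 different_continents     0.361   0.349    0.374     1449
 0.1-0.5      same_population     0.206   0.204    0.209     1278
 0.1-0.5       same_continent     0.181   0.180    0.183     1278
 0.1-0.5 different_continents     0.612   0.608    0.617     1278
panmictic expectation: (0.166, 0.167, 0.668)
```

Read: missense variants are shifted toward the sub-1% bin relative to
silent ones (0.22 vs 0.17, chi-square p ≈ 2×10⁻¹²), and two rare minor
alleles come from the *same* population two-thirds of the time — four times
the panmictic expectation of 0.166 — while common variants (0.1–0.5 bin)
approach panmixia. Both patterns are consequences of the configured
selection skew and divergence, recovered by the estimators.

The same analyses run from the shell on real or simulated data:

```bash
exonpop simulate --config sim.yaml --out cohort/
exonpop filter cohort/cohort.vcf --pipeline bc --panel cohort/panel.tsv --out kept.vcf
exonpop sharing kept.vcf --panel cohort/panel.tsv --bootstrap 1000 --seed 7 --out sharing.tsv
exonpop run --config pipeline.yaml     # simulate -> filter -> analyze -> report
```

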