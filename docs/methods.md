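# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `exonpop`, in the order data flows through the package.

## Synthetic cohort model

The generator (`exonpop.simulate`) produces multi-population diploid
genotype matrices with known per-site truth. It is a site-independent
frequency model, not a coalescent: each polymorphic site is drawn
independently, which is exactly what the downstream estimators assume
(sites are exchangeable; no linkage).

**Ancestral frequencies.** Derived-allele population frequencies follow the
standing neutral density f(x) ∝ 1/x, truncated to (1/(2·N_e), 1) with
`effective_size` N_e = 10,000 by default — one new mutation in a population
of N_e diploids, the conventional frequency floor. Sampling is by inverse
CDF: x = a^(1−u) for u ~ U(0,1), a = 1/(2N_e). Two consequences define the
generator's calibration:

* the expected unfolded sample spectrum in n chromosomes is
  E[count i] = θ·∫ C(n,i)x^(i−1)(1−x)^(n−i) dx ≈ θ/i, with relative error
  O(n/(2N_e)) concentrated in the singleton bin (&lt;1% for n ≤ 200); the
  floor therefore must sit far below one copy *in the sample* — a floor at
  1/n would depress the singleton bin by the factor (1−1/n)^n ≈ e^(−1) and
  bias Watterson's θ ≈ 13% low;
* with `theta` configured, the number of simulated sites is
  Poisson(θ·ln(2N_e)) and E[S] ≈ θ·a_(n−1), so Watterson's estimator
  recovers the configured θ (verified to ~0.1% over 100 replicates in the
  acceptance suite).

Two driving modes exist per functional class: `theta` (open site count;
sites monomorphic in the realized sample are retained and must be handled
by downstream filters, as in real call sets) and `n_sites` (a fixed count
of sample-polymorphic sites, obtained by rejection; note this conditions
the spectrum slightly and is meant for contrast/sharing experiments where
the site count matters, not for spectrum calibration).

**Selection skew.** Classes listed in `selected_classes` (default missense
and nonsense) have their ancestral frequencies multiplied by
`selection_skew` ∈ (0,1] and re-truncated at the floor. This is a
phenomenological rare-allele enrichment — a stand-in for purifying
selection that reproduces the observable (excess sub-1% mass in functional
classes), not a fitness model. Default 0.5.

**Population structure.** A two-level Balding–Nichols hierarchy: the
continental frequency is Beta-distributed around the ancestral frequency
and the population frequency around the continental one, each level with
F = `fst`/2, giving total variance p(1−p)·fst·(1−fst/4) ≈ p(1−p)·fst. This
reproduces the "similar within continent, different between" pattern that
drives the sharing statistic. Default fst = 0.08, a typical human
continental value; fst = 0 degenerates to panmixia exactly (no Beta noise).
Genotypes are Binomial(2, p_pop) per sample.

**Panels.** The default panel is seven populations in three continental
groups with sample sizes 112/108/109/107/105/90/66 (YRI, LWK, CHB, CHD,
JPT, CEU, TSI), the layout of the deep exon-capture pilot cohorts; tests
use smaller panels (documented per test) to stay desk-scale.

**Coverage.** Read depth is mean_depth · t_j · s_i rounded to integer, with
t_j log-normal per target (σ = `target_sigma`, mean 1, shared across
samples so target-to-target variance is reproducible) and s_i gamma per
sample (CV = `sample_cv`, mean 1). Defaults 48×, σ = 0.7, CV = 0.3 mimic
the strong capture-efficiency heterogeneity of exome data. Zero variances
give an exactly constant matrix — a deliberate property used in tests.

**Genotype errors.** `corrupt_genotypes` miscalls each genotype class with
configured probabilities (default: het→hom-ref 3.0%, hom-alt→het 7.7%,
hom-ref→het 0.1%, the complements of the per-class accuracies a
deep-coverage validation series reports) and returns the 3×3
called-vs-true table consumed by the validation module.

**Other conventions.** Alternate alleles are transitions with probability
0.78 (Ts/Tv ≈ 3.5, the coding-region value); the ancestral allele equals
the reference (the simulation has no ancestral misidentification — see
Limitations); the `known` flag is Bernoulli with probability rising with
frequency (0.25 / 0.55 / 0.9 below 1%, 1–10%, above 10%) to mimic database
ascertainment bias. All randomness derives from one root seed through fixed
per-operation sub-streams, so each operation is independently reproducible
and identical configs yield byte-identical outputs.

## Coordinates and formats

VCF positions are 1-based; BED intervals and all internal interval math are
0-based half-open. Multi-allelic VCF records are split into one site per
alternate allele (dosage-conserving), because every statistic here is
per-alternate-allele. Missing genotypes are excluded from numerator and
denominator of every frequency; a site's chromosome count is twice its
called samples. Consensus targets are the union of the capture designs
intersected with the exon set.

## Filters

The two filter families follow the deployed rules: quality ≥40 with at
least one non-reference genotype of GQ ≥10 (`bc_filter`); and QD ≥5 as a
pass condition with HRun &gt;3, mean heterozygote reference-allele balance
≥0.75, and membership in a cluster of ≥3 variants spanning ≤10 bases as
fail conditions (`bi_filter`). Two interpretive choices: HRun is the
maximum of the two runs adjacent to the site that share the alternate base
(either side — the artifact arises from flanking homopolymers on either
strand), and sites with no heterozygote pass the AB rule because the
statistic targets heterozygote artifacts and is undefined without them.
Indel equivalence merges same-type events within 5 bp transitively; the
cluster representative takes the leftmost position and the alleles of the
highest-allele-count member.

## Diversity and spectra

Unfolded spectra require an ancestral base matching one of the two alleles;
other sites are excluded rather than guessed. Projection to m chromosomes
keeps fractional expected counts (no rounding) and is exactly linear, hence
composition-consistent to floating-point precision. Sites genotyped in
fewer chromosomes than the spectrum's n contribute their own hypergeometric
projection; sites with more are projected down. Heterozygosity tables are
reported per callable base and ×10⁴ for display, the conventional scale on
which coding-region values read as ~2–9.

## Sharing

Minor alleles are labelled by global frequency across all included samples,
fixed *before* down-sampling (ties at 0.5 label the alternate allele
minor); the label does not flip per draw. Singletons are dropped — one
allele cannot be shared. Down-sampling reduces each population
independently by hypergeometric draws to m_p chromosomes; per AF bin the
estimate is Σ_s E[1{D_s≥2}·sharing_s] / Σ_s P(D_s≥2). Joint enumeration is
exact when the total minor count is ≤12 (configurable); otherwise Monte
Carlo with a seeded stream, and the reported MC standard errors use the
delta method for the ratio of sums. Confidence intervals are percentile
bootstrap over sites. The percentile bootstrap is slightly anti-
conservative below ~100 sites per bin; the calibration experiments
therefore use cohorts whose bins hold ≥100 sites.

## Enrichment

Bins are minor AF [0, 0.01), [0.01, 0.1], (0.1, 0.5] — boundary values fall
in the intermediate bin, matching the open labels "<0.01" and ">0.1".
Error-rate correction deflates each bin's count to its expected
true-positive count c·(1−e_b); the default rates (6.2%, 3.2%, 3.4%) map to
(low, intermediate, common) in that order. This deflation is a
reconstruction: the procedure behind published "error-rate-corrected"
contrasts is not specified anywhere we know of, so the package implements
the simplest defensible scheme and treats the corrected chi-square as a
score (fractional counts) rather than an exact count-based test.

## Validation arithmetic

Inconclusive assays are excluded from every rate denominator. Per-class
genotype accuracy is diagonal/row-total over *called* classes; the overall
accuracy is the trace ratio, which is also the count-weighted mean of the
per-class values. Display rounds to one decimal; full precision is kept
internally.

## Calibration experiments (acceptance suite and script)

Problem sizes were chosen once, as the smallest cohorts in the regime where
each estimator's asymptotics hold:

* spectrum vs θ/i: one population, 50 samples, θ = 12, 200 replicates,
  bins 1–20 within 3 SE of the replicate mean;
* θ and diversity-ratio recovery: 100 replicates, ratio of replicate means
  (a mean of per-replicate ratios would carry an upward Jensen bias);
* chi-square null: 1,000 replicates of two 300-site classes with identical
  AFS, rejection rate at α = 0.05 required in (0.03, 0.07); power: 100
  replicates at skew 0.25 with 5,000 sites per class, p < 0.01;
* panmixia: 100 fst = 0 replicates of four 50-sample populations and 2,500
  sites, percentile bootstrap (2,000 resamples); coverage of the panmictic
  expectation pooled over replicate × bin × category events must be ≥93%.

## What passing tests do and do not show

The generator shares the estimators' assumptions (independent sites,
Balding–Nichols divergence, binomial genotypes). Passing calibration
therefore demonstrates the estimators are correct *under the model*, not
that the model captures real exome data: linkage disequilibrium, coalescent
genealogical correlation, ancestral misidentification, batch effects
between sequencing centers, and capture bias correlated with variant status
are all absent. The published headline quantities that depend on the actual
study data (total SNP yield, novelty fractions, per-population
heterozygosity values, exact enrichment percentages) are out of reach of
any simulation and are not claimed; what the package reproduces exactly is
the *arithmetic* of the published validation tables and every
combinatorial identity the analyses rest on.

## Known limitations

* No coalescent structure, recombination or demography beyond the skew and
  fst knobs; the site-frequency model is equilibrium-neutral plus a
  phenomenological skew.
* Gene-model arithmetic assumes the standard nuclear genetic code;
  mitochondrial and selenocysteine-containing genes are out of scope.
* `read_vcf` materializes sites in memory; cohorts far beyond ~10⁵ sites ×
  10³ samples would need a streaming design.
* Exact down-sampling enumeration is exponential in the number of
  populations carrying minor alleles; the C ≤ 12 threshold keeps it cheap,
  and larger counts fall back to Monte Carlo.
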