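# Methods

This package implements the statistical machinery for testing potential local
adaptation between shallow (~20 m) and mesophotic (~40 m) populations of a
sessile marine invertebrate, combining microsatellite population genetics with
reciprocal-transplant and common-garden phenotypes. Because colony-level
genotype and trait data of this kind are rarely deposited, the package ships a
synthetic-data module that emulates the statistical structure of such a study,
and every stage is validated against independent oracles and parameter
recovery on those simulations.

## Genetic differentiation (theta)

F_ST is estimated by the Weir–Cockerham (1984) moment estimator theta. Per
locus and allele, the variance in allele frequency is partitioned into
components a (among populations), b (among individuals within populations)
and c (within individuals), computed from locus-specific typed sample sizes
n_i, allele frequencies p_iu and heterozygote frequencies h_iu. The
multi-locus estimate is the ratio of summed a over summed (a + b + c) — the
standard ratio-of-sums convention. Loci that cannot support the estimator
(monomorphic, fewer than two typed populations, n̄ ≤ 1) contribute nothing
and are flagged in the per-locus table. Missing data are handled by
locus-specific sample sizes; no null-allele (ENA-style) correction is applied
— theta runs on observed genotypes, on the premise that loci prone to null
alleles are filtered before analysis. This is a documented limitation, not an
omission: the pipeline's scope begins after locus selection.

**Confidence intervals.** The 95% CI comes from bootstrapping loci. The
default interval is an equal-tailed studentized bootstrap-t: each locus
resample is studentized by its own delete-one-locus jackknife SE of the
ratio-of-sums, and the observed jackknife SE scales the t-quantiles. The
plain percentile interval (2.5/97.5) is available via
`method="percentile"`. The studentized default was chosen on calibration
grounds: per-locus divergence is right-skewed, and in coverage simulations at
the conditions this package targets (2 populations × 50 diploids × 20 loci,
F between 0.02 and 0.14) the percentile interval covers the generating F in
only ~87–89% of replicates, almost always missing below the true value, while
the studentized interval reaches ~91–93%. With a single usable locus both
methods return the degenerate interval (theta, theta).

## Diversity statistics

Per sample and locus: Ho is the observed heterozygote fraction; He is Nei's
unbiased gene diversity (2n/(2n−1))(1 − Σp²); allelic richness Ar(g) is
hypergeometric rarefaction to g gene copies, Σ_u [1 − C(N−N_u, g)/C(N, g)],
exactly the mean allele count over all C(N, g) subsamples (verified against
exhaustive enumeration). g defaults to 64 genes (32 diploids) in the study
drivers, the depth supported by samples of ≥42 diploids with some missing
calls; the library default is twice the smallest per-locus typed count.

The inbreeding estimator f is the Weir–Cockerham within-sample statistic,
1 − Σc/Σ(b+c) over loci and alleles. Its panmixia test, and the
linkage-disequilibrium and genotypic-differentiation tests, are Monte-Carlo
permutation tests rather than Markov-chain "exact" tests: the same nulls
(random union of gametes within samples; independence of two-locus genotypes;
exchangeability of individuals among populations), but seed-reproducible and
with the add-one p-value rule p = (1 + #{T* ≥ T}) / (1 + n_perm), which keeps
every p in [1/(n_perm+1), 1]. Association statistics are G (log-likelihood
ratio) on the relevant contingency tables, summed over loci where applicable.
Test batteries are corrected by Benjamini–Hochberg FDR (the default meaning
of "FDR correction" in this literature), delegated to statsmodels.

## Effective population size (LD method)

Contemporary Ne per sample follows Hill's linkage-disequilibrium method with
Waples' bias correction under random mating. For every locus pair and every
pair of alleles with sample frequency ≥ the screening cutoff (default 0.02),
the composite Burrows disequilibrium is estimated from unphased dosages —
Δ̂ = (n/(n−1)) · cov(x, y)/2 — and squared into r² = Δ̂²/(p(1−p)q(1−q)).
Locus-pair mean r² values are combined with weights equal to each pair's
number of independent allele comparisons, (K_A−1)(K_B−1) (an unweighted mean
is available for sensitivity checks); S is the matching weighted harmonic
mean sample size. The sampling expectation 1/S + 3.19/S² (S ≥ 30; the S < 30
branch 0.0018 + 0.907/S + 4.44/S² is also implemented) is subtracted and Ne
recovered by inverting Waples' quadratic. A non-positive drift component
yields a negative estimate, reported as-is: it means drift leaves no
detectable LD signal at this sample size, the expected outcome for large
populations. The 95% CI is a delete-one jackknife over locus pairs on the
weighted mean r², pushed through the same transformation; the upper bound is
infinite exactly when the lower r²-drift bound is ≤ 0.

**Known limitation.** The published 1/S + 3.19/S² expectation was calibrated
for the original program's estimator. For the estimator variant documented
above, second-moment theory puts the null mean of r² at ≈ 1/(S−1), so the
correction over-corrects by roughly 4% of the subtracted term (≈ 0.001 at
S = 45). Consequences: null (large-Ne) simulations return slightly negative
mean r²-drift, reinforcing the negative/infinite signature, and point
estimates at moderate true Ne carry a modest upward bias (median ≈ 80 over
replicates at true Ne = 50, S = 50, 30 loci — within the factor-two band that
matters for the method's qualitative conclusions). The test suite asserts
practical centering (≥ 95% of the sampling component removed) rather than
exact centering.

## Permutational ANOVA of phenotypes

For a univariate response the PERMANOVA pseudo-F on Euclidean distance equals
the classical ANOVA F on the same SS partition; the implementation works
directly on the response and is unit-tested against statsmodels' ANOVA to
1e-10. The transplant design is the crossed 2×2 fixed-factor layout (origin
depth × treatment depth) with interaction; the common garden is one-way
(origin depth) on the final necrosis level. Null distributions are
permutation-based (default 9999 permutations, add-one rule): raw observations
are permuted for main effects and one-way tests; the interaction permutes
residuals of the additive reduced model — a standard choice the source
software does not document, recorded here as a deliberate substitution. Sums
of squares are the Type I partition, which is unambiguous on balanced data;
unbalanced cell counts are refused rather than silently re-weighted, and
experimental plates are not modelled as a nested random factor (a
limitation). A constant response is reported as the degenerate table
(pseudo-F 0, p 1) rather than an error.

Colony growth is aggregated as the mean of the k (default 10) greatest
labelled-band-to-periphery distances; fewer than k measurements fall back to
the mean of all with a warning.

## P_ST–F_ST comparison and sensitivity analysis

P_ST approximates Q_ST from phenotypes alone:

    P_ST(r) = r·σ²_B / (r·σ²_B + 2·σ²_W),   r = c/h²,

with σ²_B and σ²_W the among- and within-sample variance components of the
trait (method-of-moments from the one-way random-effects ANOVA;
σ²_B = max(0, (MS_B − MS_W)/n₀) with the standard unbalanced-design n₀ —
negative moment estimates are truncated so P_ST stays in [0, 1]), h² the
within-population narrow-sense heritability and c the across-population
additive proportion, both unknowable without breeding designs. The null
assumption is r = 1; robustness is probed on the conservative range
0 < r ≤ 1 over a 200-point log-spaced grid on (0.001, 1].

Bootstrap CIs resample individuals with replacement within each sample
(stratified; sample sizes preserved; default 1000 replicates) and recompute
the full curve; replicates with zero within-sample variance everywhere are
degenerate (P_ST ≡ 1), counted, and flagged above 1%. "Significantly higher
than F_ST" is operationalized as the lower 95% percentile bound of P_ST
exceeding the reference point value — the reference being the upper 95%
bound of theta, or an external allozyme-based F_ST (default 0.1) used as a
conservative ceiling for neutral differentiation. (c/h²)_crit is the
smallest r whose lower bound exceeds the reference, linearly interpolated
between bracketing grid points; values below 0.2 are flagged robust per the
published guideline, and raising the reference can never lower crit. The
bootstrap resamples trait values within strata only (the within-sample
reading of the resampling description); BCa intervals were not used because
the comparison logic needs plain quantile bands per grid point.

## Synthetic data

The generators define the study conditions and emulate structure, not
biology:

- **Genotypes** follow a Balding–Nichols island model: ancestral frequencies
  from a symmetric Dirichlet (10 alleles/locus by default), population
  frequencies from Dirichlet(p_anc(1−F)/F). F may be population-specific;
  the defaults (0.02, 0.05, 0.17, 0.13 for the four samples of 43/43/42/45
  diploids at 7 loci) place pairwise theta across roughly 0.03–0.15 with
  global theta near 0.10 — the weakly differentiated within-locality pair
  and the strongly drifted second-locality samples of the study design.
  Optional inbreeding (autozygosity probability f) and null alleles (a
  hidden allele making carriers apparently homozygous and double-null calls
  missing) are available for robustness experiments; microsatellite mutation
  is not modelled.
- **Wright–Fisher cohorts** (for Ne recovery tests): one generation of random
  mating within a finite diploid parent pool, each offspring from a distinct
  random parent pair.
- **Transplant growth**: cell means over the 2×2 design plus Normal(0, σ²_W)
  noise, 10 colonies per cell. Defaults realise the local-vs-foreign pattern
  with σ²_W = 4.1e-4 (a typical residual mean square for millimetre-scale
  growth) and between-origin contrasts that put P_ST(1) near 0.42 in the
  shallow habitat and 0.06 in the mesophotic one — a study-like effect
  structure.
- **Common-garden necrosis**: a phenomenological threshold model. Daily
  temperature follows a half-sine summer anomaly peaking at 26 °C (~77
  degree-days above the 24 °C necrosis threshold over 120 days); per colony,
  necrosis is 0 until cumulative degree-days exceed a lognormal onset lag,
  then rises linearly at a lognormal slope, capped at 100%. Origin-specific
  medians (lag 100 dd / slope 5 for shallow-origin, lag 12 dd / slope 3 for
  mesophotic-origin, lognormal sd 0.6) put expected survival near 84% vs 16%
  and the shallow never-necrosed fraction near two thirds — the differential
  phenotypic buffering the common garden is designed to expose. The model is
  not physiological; its job is to produce trajectories with the right
  ordering, separation and variance.

What passing tests on these simulations do **not** show: robustness to
null-allele-driven heterozygote deficits (real microsatellite panels are
pre-filtered for this), to genotyping error, to non-normal or heteroscedastic
trait noise, to plate effects, or to family structure within samples (which
biases LD-based Ne downward). The generators are reproducible from
(config, seed) throughout.

## Pipeline and reproducibility

`run_study` executes the stages in dependency order (diversity → theta/CI →
Da/NJ phenogram → Ne → PERMANOVA → P_ST–F_ST), records per-stage status, and
skips dependent stages with a reason instead of aborting. One global seed is
expanded into per-stage child seeds via `numpy.random.SeedSequence.spawn`, so
stages can be rerun in isolation; reports regenerate bit-identically from the
same config. Neighbor joining is delegated to scikit-bio (negative branch
lengths clamped to zero); bootstrap support for the phenogram resamples loci
and counts recovered bipartitions. In the pipeline's P_ST stage the
theta-based reference is the maximum pairwise upper CI bound — a conservative
single reference for comparisons that pool origins across localities; the
library functions accept any per-pair reference directly.

Problem sizes in the test suite (e.g. 100 replicate datasets per F for
coverage, 500 replicates for component recovery, 50 Wright–Fisher cohorts per
Ne scenario, 1000 null simulations × 999 permutations for test calibration)
were chosen as the smallest designs at which the Monte-Carlo error of each
check is comfortably below the tolerance being asserted.
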