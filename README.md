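# margin-adapt

Statistical machinery for testing potential local adaptation between shallow
and mesophotic populations of sessile marine invertebrates (red-coral-style
study systems), from microsatellite genotypes and transplant/common-garden
phenotypes.

Depth-transplant studies ask whether populations a hundred metres apart are
locally adapted — a question with direct consequences for the "deep refugia"
idea that mesophotic populations can replenish disturbed shallow ones. The
inference chain couples neutral genetic differentiation with phenotypic
differentiation:

- **θ (Weir–Cockerham)** — the F_ST moment estimator from variance components
  a, b, c, with ratio-of-sums multilocus combination and bootstrap-over-loci
  CIs; genotypic differentiation permutation tests; Nei et al. (1983) Da
  distances and a neighbor-joining phenogram with bootstrap support.
- **Diversity table** — Ho, unbiased He, Weir–Cockerham f (F_IS) with a
  permutation test of panmixia, rarefied allelic richness Ar(g), and an
  LD test battery with Benjamini–Hochberg FDR control.
- **Ne (LD method)** — contemporary effective size from Burrows composite
  disequilibrium (Hill's method with Waples' bias correction, random mating,
  2% allele-frequency screening, jackknife CIs over locus pairs); negative
  estimates with infinite upper bounds mean "no detectable drift signal".
- **PERMANOVA** — one-way and two-factorial (with interaction) univariate
  permutational ANOVA on Euclidean distance; for univariate responses the
  pseudo-F equals the classical ANOVA F, but p-values come from permutation.
- **P_ST–F_ST** — the core comparison:
  `P_ST(c/h²) = (c/h²)·σ²_B / ((c/h²)·σ²_B + 2σ²_W)`, bootstrap CIs by
  resampling individuals within samples, significance against θ's upper CI
  bound and an external allozyme F_ST, and the (c/h²)_crit sensitivity
  analysis (crit < 0.2 ⇒ robust evidence of divergent selection on the
  trait).
- **Synthetic data** — Balding–Nichols genotypes (population-specific F),
  Wright–Fisher cohorts, 2×2 transplant growth, and threshold-model
  common-garden necrosis, so the whole pipeline runs and is tested without
  any external data.

## Worked example

Run the numbered drivers in order (each writes CSVs under `results/`):

```bash
python analysis/01_simulate_study.py --seed 1   # synthetic study dataset
python analysis/02_diversity_table.py
python analysis/03_differentiation.py
python analysis/04_effective_size.py
python analysis/05_transplant_anova.py
python analysis/06_pst_fst_comparison.py
```

The last step prints, for the shallow habitat of the transplant experiment
(seed 1):

```
theta upper 95% bound (max over pairs): 0.193

growth, shallow habitat: P_ST(c/h2=1) = 0.71 (95% CI 0.53-0.88)
     reference   fst  significant_at_null  crit_r  robust_below_0.2
theta_upper_CI 0.193                 True   0.213             False
  allozyme_FST 0.100                 True   0.099              True
```

Reading: under the null genetic-architecture assumption (c/h² = 1) the
phenotypic differentiation in growth between origins, measured in the shallow
habitat, is far above neutral expectation (lower CI 0.53 vs θ upper bound
0.193). The sensitivity analysis says the conclusion survives down to
c/h² ≈ 0.21 against the θ bound and ≈ 0.10 against the allozyme reference —
the latter below the 0.2 robustness guideline, i.e. evidence of divergent
selection on growth that does not hinge on optimistic heritability
assumptions. In the mesophotic habitat P_ST is indistinguishable from zero
and no c/h² ≤ 1 reaches significance, the contrast that makes the pattern
"local vs. foreign" rather than uniform.

Equivalently, `margin-adapt run --seed 1 --out results/run` executes all
stages from one config and writes a combined JSON/markdown report, and the
same machinery is importable (`from margin_adapt import pst_bootstrap, ...`).

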