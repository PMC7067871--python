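# dioecia

Spatial population genetics of mapped dioecious tree stands.

Tropical dioecious trees are insect-pollinated, vertebrate-dispersed and
obligately outcrossing; how far pollen and seeds actually move — and
which seedlings survive distance-dependent (Janzen–Connell) mortality
near their parents — shapes the fine-scale genetic structure (FSGS) of a
stand and the realized fitness of individual trees.  `dioecia`
implements the full analysis pipeline for a tagged, geo-referenced,
genotyped population inside a rectangular plot:

- **Demography** — sex ratios as proportion male with G goodness-of-fit
  tests, the replicated-G heterogeneity test across diametric cohorts
  (Σᵢ Gᵢ = G_pooled + G_het), and Kolmogorov–Smirnov comparison of male
  vs female diameter distributions.
- **Genetic diversity** — Na, allelic richness by rarefaction,
  Ho, unbiased He = n/(n−1)(1 − Σ pₐ²), fixation index F = 1 − Ho/He
  with a bootstrap-over-loci CI.
- **FSGS** — Loiselle pairwise kinship F_ij, distance-class
  autocorrelograms with permutation envelopes, regression of F_ij on
  ln d_ij with jackknife-over-loci SE, the intensity statistic
  **Sp = −b_log / (1 − F₁)**, and a between-cohort variant
  (seedlings × large adults).
- **Spatial interaction** — bivariate Ripley K₁₂(t) with isotropic
  rectangle edge correction, L₁₂(t) = √(K₁₂/π) − t, and random-labeling
  envelopes (association where L > upper, repulsion where L < lower).
- **Parentage** — exclusion probabilities from allele-frequency moments,
  Marshall-style multilocus LOD paternity and parent-pair assignment
  with a genotyping-error model P(g|parents) = (1−ε)·Mendel + ε·HWE and
  simulation-calibrated 95%/80% confidence tiers.
- **Dispersal** — effective (embryo paternity) vs realized (seedling
  parent-pair) pollen and seed kernels, band proportions, kernel
  comparisons, and progeny-count fitness regressions.
- **Simulator** — a spatially explicit forward model (exponential pollen
  and seed kernels, logistic Janzen–Connell thinning on the distance to
  the nearest parent, HWE-replacement genotyping error) whose known
  pedigree is the ground truth every estimator is validated against.

## Worked example

Simulate a 30 ha study (1000 × 300 m), then analyse it:

```bash
dioecia simulate --seed 3 --out-prefix run1
dioecia demography run1.population.csv
dioecia fsgs run1.offspring.csv --classes 25,50,100,200 --perms 999
```

The demography table for this run prints:

```
                scope  males  females  prop_male      stat  df        p
            cohort II     86       53   0.618705  7.909841 1.0 0.004917
           cohort III     48       23   0.676056  8.994388 1.0 0.002708
               pooled    134       76   0.638095 16.229187 1.0 0.000056
        heterogeneity    134       76        NaN  0.675042 1.0 0.411299
dbh KS male vs female    134       76        NaN  0.092694 NaN 0.769369
```

a male-biased stand overall (64% male, G = 16.2, p < 0.001) whose bias
does not differ between the adult cohorts (G_het = 0.68, p = 0.41), with
no detectable intersex difference in diameters (KS D = 0.09).  The FSGS
command reports, per distance class, the mean kinship among the 105
established seedlings with its 95% permutation envelope,

```
 lower  upper  n_pairs   mean_f   env_low  env_high     p
   0.0   25.0       28 0.004555 -0.024800  0.036505 0.910
  25.0   50.0       96 0.013516 -0.010687  0.022062 0.300
  50.0  100.0      376 0.004812 -0.003353  0.013241 0.948
 100.0  200.0     1067 0.004859  0.000864  0.009487 0.932
b_log=-0.00296 (jackknife SE 0.00227, perm p=0.0440) F1=0.0046 Sp=0.0030
```

— weak structure (every class mean inside its envelope, Sp = 0.003 on
the low end of the range reported for animal-dispersed trees), as
expected when both kernels are long relative to the plot.

Other subcommands: `validate`, `diversity` (Table-style per-cohort
output), `ripley` (bivariate L₁₂ with verdicts per distance),
`parentage` (paternity or parent-pair assignment tables) and
`dispersal` (kernel summaries and band proportions).  Everything is also
available as a library (`import dioecia`).

## Documentation

`docs/methods.md` describes the models, estimators, defaults, numerical
choices and known limitations in detail.
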