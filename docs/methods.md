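# Methods

`dioecia` analyses a mapped, sexed, genotyped population of a dioecious
tree inside a rectangular plot, and ships a forward simulator whose known
pedigree serves as ground truth for every estimator.  This note records
the models, the defaults and why, the numerical choices, and the known
limitations.

## Data model

Individuals carry planar coordinates (m), stem diameter (dbh, cm; basal
diameter for plants under 2 m), a sex label (`male`/`female`/
`undetermined` — the latter for stems that never flowered during the
census), an optional diametric cohort and an unordered integer allele
pair per microsatellite locus.  Cohorts default to I = [0, 10) cm,
II = [10, 20] cm, III = (20, ∞) cm; the boundary ownership is
configurable (`SizeClassRule`) because field studies are rarely explicit
about stems landing exactly on a cut-point.  A genotype with either
allele unread is treated as missing at that locus by every estimator;
nothing is imputed.

## Demography

Sex ratio is the proportion male among sexed stems, males/(males+females).
Departure from 1:1 uses the likelihood-ratio G goodness-of-fit test
(G = 2 Σ O ln(O/E), 0·ln 0 ≡ 0, df 1, chi-square tail; an exact binomial
option exists for small counts).  Homogeneity across cohorts uses the
replicated-G decomposition Σᵢ Gᵢ = G_pooled + G_het with df k−1 — the
additivity is tested property-wise on arbitrary inputs.  Intersex
diameter-distribution differences use the two-sample Kolmogorov–Smirnov
test with the asymptotic p-value; exact small-sample p is out of scope.

## Genetic diversity

Per locus: allele count Na, observed heterozygosity Ho, unbiased expected
heterozygosity He = n/(n−1)·(1 − Σ pₐ²) with n the gene count, and
F = 1 − Ho/He.  The multilocus F is 1 − mean(Ho)/mean(He) over polymorphic
loci (the ratio-of-means weighting; alternatives would be per-locus means
of F, which over-weight low-He loci).  Allelic richness uses hypergeometric
rarefaction Ar(g) = Σₐ [1 − C(N−Nₐ, g)/C(N, g)], with g defaulting to the
smallest per-locus gene count across the cohorts being compared.
Confidence intervals for F come from a percentile bootstrap over loci.

*Limitation*: with only ~9 loci the percentile bootstrap undercovers —
measured ≈86% for a nominal 95% interval under Hardy–Weinberg simulation
(BCa is no better at 84%).  Coverage approaches nominal as the panel
grows (≈90% at 40 loci); both behaviors are pinned by tests.  Intervals
from small panels should be read as optimistic.

## Fine-scale genetic structure

Pairwise kinship uses the Loiselle-type estimator: per locus, with allele
dosages x ∈ {0, ½, 1} and reference frequencies pₐ from n individuals,

    F_ij,l = Σₐ [(x_ia − pₐ)(x_ja − pₐ) + pₐ(1−pₐ)/(n−1)] / Σₐ pₐ(1−pₐ),

combined across loci with weights Σₐ pₐ(1−pₐ); a pair missing a locus
drops that locus from numerator and denominator.  This estimator is the
standard companion of the Sp framework and is robust to rare alleles.
Note a finite-sample property verified analytically and by simulation:
with frequencies estimated from the sample itself, the all-pair mean is
+1/(2(n−1)) (the closure term −Var(x)/(n−1) is overcompensated by the
+pₐ(1−pₐ)/(n−1) correction), not zero and not −1/(n−1); it vanishes as
O(1/n).

The autocorrelogram bins pairs into half-open (lower, upper] distance
classes — default 20 m steps to 100 m then 25 m steps to 200 m — and
tests each class mean against a null built by permuting genotypes over
the fixed coordinates (equivalent to permuting individuals in space).
Envelopes are order statistics: with m = ⌊α/2·(n_perm+1)⌋ the m-th
smallest/largest null value, so a null observation escapes with
probability ≈ α (verified: 400-simulation type-I error 5% ± 2%).
P-values are two-sided permutation ranks with a small tie tolerance
(1e−9 relative) so that degenerate nulls — e.g. a single class holding
every pair, whose mean is permutation-invariant up to float summation
order — report p = 1.

The regression of F_ij on ln d_ij runs over all pairs (not class means);
co-located pairs (d = 0) are excluded with a warning.  Slope SE comes
from a delete-one-locus jackknife, significance from the same
genotype-permutation null.  Sp = −b_log/(1 − F₁) with F₁ the first-class
mean kinship; the identity is exact by construction and tested bitwise.
The between-cohort variant restricts to inter-cohort pairs, takes
reference frequencies from the union and permutes genotypes over the
union's locations.

Reference allele frequencies for a per-cohort analysis default to the
analyzed cohort itself (a flag overrides); the spec of the distance
classes and the ≤200 m regression restriction are configurable.

## Bivariate Ripley K

K₁₂(t) = |A|/(n₁n₂) · ΣᵢΣⱼ 1(d_ij ≤ t)/c_ij with circles centered on
class-1 points and Ripley's isotropic rectangle correction: each near
edge removes an arc 2·arccos(d/r), adjacent arcs overlap by
arccos(a/r) + arccos(b/r) − π/2 when the corner lies inside the circle.
The closed form is tested against brute-force perimeter sampling and the
estimator against its CSR expectation πt² (within 5% at t = 25, 50 m
over 200 simulations in the 1000 × 300 m window).  The variance-stabilized
L₁₂(t) = √(K₁₂/π) − t is zero-centered under independence, so
association reads as L > 0.  The null is random labeling: pooled
locations fixed, labels reassigned; envelopes are the same order-statistic
bands.  t is restricted to half the shorter window side (the correction's
validity bound); the default grid is 5–150 m in 5 m steps.  Centering on
class-1 circles is the default; a symmetrized ½(K₁₂+K₂₁) option makes the
estimate exactly label-exchange invariant.

## Parentage

The error model is a single per-locus rate ε: with probability ε the
observed genotype is an independent Hardy–Weinberg draw at the reference
frequencies, so P(g_o | parents) = (1−ε)·Mendel + ε·HWE.  The simulator
injects exactly this process, so the likelihood is generatively matched.
Parent genotypes are taken as observed (parental error folds into ε).
A locus missing in offspring or a scored parent contributes likelihood 1.

Paternity LOD (known mother): Σ_l ln[P(g_o|g_m, candidate)/P(g_o|g_m,
random male)].  Parent-pair LOD: Σ_l ln[P(g_o|g_f, g_m)/P_HWE(g_o)];
dioecy fixes the roles, the female member of the best pair is the
mother.  Confidence tiers (95%, 80%) are calibrated by simulation:
offspring are generated with the true father (pair) alternately inside
and outside the candidate pool, and the threshold is the lowest LOD at
which the cumulative best-candidate accuracy, walking down from the top,
still meets the tier.  Ties within 1e−9 LOD are left unassigned.  With
ε = 0 a uniquely compatible candidate is assigned outright (pure
exclusion logic); incompatible candidates have LOD −∞ and exclusion and
likelihood verdicts agree exactly.

Exclusion probabilities (random unrelated candidate excluded as sole
parent, as second parent given a known parent, and as a pair) are
computed from allele-frequency moments in closed form and combined as
1 − Π(1 − Q_l).  The closed forms are verified against exhaustive
genotype enumeration to 1e−12.

The mismatch-based ε estimator (fraction of co-typed mother–offspring
locus comparisons sharing no allele) is downward-biased relative to the
generative ε: an erroneous genotype often still shares an allele with
the mother by chance.  The estimator faithfully reports the mismatch
rate; users calibrating ε from duos should treat it as a lower bound.

## Dispersal kernels and the Janzen–Connell probe

Three samples: effective pollen (paternity on seeds collected from known
mothers — before dispersal and establishment), realized pollen and
realized seed (parent-pair assignment on established seedlings).
Distances are mother–father for pollen modes and offspring–mother for
seed.  Band proportions default to {≤150, 150–600, >600} m.  Kernel
comparisons add a two-sample KS statistic — an extension; the field
narrative compares proportions only — plus a stochastic-dominance
verdict at the band breaks.  Unassigned offspring are counted alongside
every kernel (out-of-plot parents).  Fitness regressions are plain OLS
of per-adult established-progeny counts on dbh or distance.

## The simulator

Adults are uniform in the window; sex is Bernoulli (default proportion
male 0.6, a plausible male-biased value — the source system reports
male bias without a usable pooled figure); diameters are lognormal above
10 cm so adults span cohorts II/III, and seedlings are assigned small
diameters (cohort I).  Founder allele frequencies are flat-Dirichlet
over 7 alleles at 9 loci (expected He ≈ 0.75; `dirichlet_concentration`
≈ 0.2 reproduces the He ≈ 0.5 typical of field microsatellite panels).
Mating: mother uniform among females, father ∝ exp(−d/λ_p) (default
λ_p = 300 m, the scale of observed effective pollen means); offspring
genotypes are exact Mendelian draws.  Seed deposition displaces from the
mother by an Exponential(λ_s = 150 m) distance with uniform direction,
rejection-sampled to stay in the window — so the realized kernel is
window-truncated exactly as a field plot truncates observation.
Establishment is Bernoulli with s(d*) = logistic((d* − d₅₀)/slope),
d* = min(distance to mother, distance to father), defaults d₅₀ = 150 m,
slope = 30 m — both parents' neighborhoods depress recruitment.
Genotyping error and missingness (defaults 0.0923 and 0.02) are applied
to observed genotypes only; the truth table keeps the pre-error state.

What the generator does *not* emulate: overlapping generations, growth,
mutation, selfing (the species is dioecious), polyploidy, anisotropic or
fat-tailed (2Dt/lognormal) kernels, directed dispersal to roosts, and
spatially autocorrelated adult placement.  Passing tests therefore
demonstrate estimator correctness under a clean leptokurtic-kernel,
uniform-habitat model, not robustness to every field complication.

### Strength of the Janzen–Connell signature

Because survival filters the *seedling-to-parent* distances, the seed
kernel carries the full effective→realized signature (the ≤150 m mass
drops in essentially every replicate).  The pollen (mother–father)
distance is filtered only indirectly, through the chance that a
deposition site falls inside the father's mortality zone; its expected
≤150 m drop is real but an order of magnitude smaller (≈ +1.6 ± 0.2
percentage points at these defaults, ~73% of replicates directionally
correct).  The acceptance checks therefore pin the per-replicate
criterion on the seed kernel and the pollen effect as a mean directional
drop across replicates, with per-replicate seed crops of 2000 so the
Monte Carlo resolves that mean.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen for stable
Monte Carlo estimates: permutation nulls of 99–999 (10,000 remains the
analysis default), 200–400 replicate simulations for calibration checks,
500 simulated offspring with 100 candidate males for paternity recovery,
and 20 replicates for kernel signatures.  Envelope bounds use order
statistics rather than interpolated percentiles so the escape
probability is exact under exchangeability.  All randomness flows
through `numpy.random.Generator` seeds; identical seeds reproduce every
output byte-for-byte.
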