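# Methods

## Scope

`rngxe` implements a two-step reaction-norm analysis of genotype-by-
environment interaction (GxE) for livestock phenotypes: herd-environment
gradient estimation with an animal model, a random-regression sire model on
that gradient with heterogeneous residual variances, gradient summaries of
genetic variance (ZGZ′), and multivariate selection response per
environment.  Confirmatory factor analysis of type traits, climate (THI)
covariates, genomic evaluation and multi-trait samplers are out of scope.

## Models

### Step 1 — environmental gradient

Test-day data: y = HEG + htd + fixed + a + Pe + e, with HEG (herd ×
environmental group) fixed, herd-test-day `htd` IID random, `a` additive
genetic with pedigree precision A⁻¹, `Pe` IID per cow, homogeneous residual.
Single-record (conformation) data replace `htd` by a herd-year-classifier
term and drop `Pe`.  Animal-model heritability is
h² = σ²_a / (σ²_cg + [σ²_Pe] + σ²_a + σ²_e).  The posterior means of the
HEG solutions (reference level fixed at zero) are min–max scaled to
[−1, 1]; skewness, kurtosis and an omnibus normality p-value are reported
for the solution distribution.

### Step 2 — reaction-norm sire model

The HEG class effect is replaced by a fixed first-order Legendre regression
on the scaled gradient; each sire carries a random (intercept, slope) with
unstructured 2×2 covariance G₀, pedigree-structured across sires.  Residuals
fall in five classes cut at record-level quantiles of the herd's HEG
solution; the reported residual variance is the class average.  Without the
GxE term the sire effect is a plain (pedigree-structured) intercept with the
same residual classes.  Ratios G/P, GxE/P, covGxE/P and h²_sire = 4σ²_G/σ²_P
are computed chain-wise and summarised as posterior mean, SE, z = mean/SE,
and two-tailed normal p — the convention of testing a posterior against
zero by its own SD.

EBV at environment x is intercept + slope·x.  Accuracy is
√(1 − PEV/σ²_G) with PEV the posterior variance of the sire's intercept
chain.  A literal "squared-EBV" PEV variant exists behind
`pev_mode="ebv_squared"` for comparison only: it ties accuracy to EBV
magnitude and can exceed the admissible range, so it is not the default.

### Gradient summaries and selection response

ZGZ′ at a HEG level with covariate x is (1, x) G₀ (1, x)′; per-level
h²_sire uses the residual variance of the level's gradient-quantile class.
Level means within each environmental category or group are plain averages
of the contributing HEG levels.  For significance testing, estimates outside
mean ± 2 SD (computed trait-wide over all HEG levels) are discarded first —
extreme gradient endpoints otherwise dominate — and a one-way fixed-effects
GLM yields least-square means, the overall F-test and pairwise contrasts
(unadjusted two-tailed p; Tukey HSD behind a flag, since no multiplicity
adjustment is part of the core procedure).

Selection response uses b = P⁻¹Ga_s, σ_i = √(b′Pb), R = (i/σ_i)·Gb,
R_dsi = R/σ_P.  A printed variant of the response formula that contracts
G b to b′P⁻¹ is dimensionally inconsistent with a per-trait response and is
not implemented; the form used here reduces exactly to R = i h² σ_P for a
single trait and agrees with a 200,000-individual truncation-selection
Monte Carlo within simulation error (both are asserted in the acceptance
suite).  Environment-specific G matrices take the averaged ZGZ′ of the
environment's HEG levels as genetic variance; P adds the permanent-
environment, contemporary-group and class-average residual components.
Performance-test traits keep fixed station variances in every environment
(no GxE by design of station testing).  Covariances follow
σ₁₂ = r₁₂·√(σ²₁σ²₂) from supplied correlation matrices.  Default index
emphasis: 0.65 on milk yields split 3:1 PY:FY, 0.20 split equally between
the two udder/muscularity factor scores, 0.15 on performance-test traits
split 0.45 ADG / 0.55 FL×DP, somatic cell score carried at weight 0.
Selection intensity i = φ(Φ⁻¹(1−p))/p; p = 0.10 gives 1.755.

## Gibbs sampler

Location parameters are updated by a single-site sweep (numba-compiled)
over the full coefficient vector, maintaining the residual vector in place;
fixed effects use reference-level constraints against an explicit intercept.
Scalar variances have scaled inverse chi-square full conditionals; the 2×2
random-regression covariance an inverse-Wishart; residual classes
class-specific inverse chi-squares.  Default chain protocol in the analysis
scripts is 20,000 iterations, 4,000 burn-in, thinning 10 (retained =
⌊(n − burn)/thin⌋); all draws derive from one seeded generator, and
effective sample size is reported per chain as the convergence diagnostic
(no automatic stopping).

Three additions beyond the textbook scheme are load-bearing:

1. **Hierarchical centering.**  When every cow sits at a single gradient
   value, her permanent-environment effect can absorb her sire's entire
   contribution, and single-site Gibbs stalls on that ridge.  The Pe term
   is therefore parameterized as the cow's total effect centered on the
   sire reaction norm (prior mean intercept + slope·x), with the sire
   blocks redrawn exactly from their bivariate full conditionals given the
   cow effects.  Centering is applied automatically and only when the sire
   and covariate are constant within cow.
2. **Group scale moves.**  A Metropolis step on the joint rescaling
   (U_t, G₀) → (cU_t, D G₀ D) of each coefficient column and the
   covariance — the prior quadratic form is invariant, so the conditional
   for c is one-dimensional and cheap — breaks the slow random walk between
   shrunken coefficients and a small sampled covariance.
3. **Marginal relationship structure.**  The sire relationship matrix is
   built over the full ancestor pedigree but marginalized (A subsetted and
   inverted) to the sires with daughters.  This is the identical model;
   carrying data-free ancestor levels instead makes them dominate the
   covariance update and freezes the chain.

Priors: flat on every variance (scaled inverse chi-square with df −2, scale
0) and flat on G₀ (inverse-Wishart with df −(m+1) = −3, zero scale).  A
seemingly harmless "weakly informative" inverse-Wishart with small positive
df and near-zero scale is in fact proportional to |G₀|^−3 and piles prior
mass at zero, visibly biasing the GxE variance downward at these data
sizes; the flat convention removes that bias.  A fully collapsed state
(G₀ ≈ 0 exactly) is absorbing for any sampler of this family; chains start
at a tenth of the phenotypic variance and do not enter it in practice, but
degenerate starts near zero should be avoided.

## Synthetic herd-book

The generator emulates the data structure of a small dual-purpose cattle
population: herds draw environmental-category levels from area-conditional
tables (plain farms lean to loose housing / total mixed ration / no
pasture; mountain farms the reverse), the EG label is the concatenation of
the four levels, and true herd effects are spread evenly over a configured
range, min–max scaled to give the true covariate.  Sires sit on a pedigree
with two known ancestral generations; (intercept, slope) pairs are drawn
jointly as vec(U) ~ N(0, G₀ ⊗ A) so relatives have correlated reaction
norms.  Cows (dams unknown) receive their sire's transmitting ability plus
a within-family deviation N(0, 3σ²_G) — exactly the Mendelian variance of
an animal with known sire and unknown dam, so both the step-1 animal model
and the step-2 sire model are correctly specified.  Records compose herd
effect + herd-test-day + parity class + sire norm at the herd's covariate +
within-family + permanent environment + a residual from the herd's true
quintile class.

Two deliberate realism gaps matter for interpretation: the within-family
deviation is constant per cow, so under a sire model it is absorbed by Pe —
the estimable Pe truth is σ²_pe + 3σ²_G, and `sire_model_truth()` reports
the estimable components; and residual classes are assigned from true herd
effects in simulation but re-derived from estimated solutions in analysis,
so mid-class boundaries blur slightly (visible as occasional coverage loss
for the middle class only).  The generator does not simulate herd switching
between environmental groups, selection, culling, seasonal lactation-curve
shape, or genomic data, so passing tests say nothing about those features
of real data.

Default sizes (60 herds, 100 sires, 10 daughters/sire, 8 records/cow,
G₀ = [[0.06, 0.01], [0.01, 0.04]], σ²_pe = 0.1, σ²_htd = 0.05, residual
classes 0.8–1.2 on the factor-score scale, herd effects over [−1, 1]) are
the desk-scale study conditions used across the tests and analyses; the
tests' parameter-recovery study runs ten replicates of this design with
20,000-iteration chains.

## Pedigree utilities

A⁻¹ is assembled directly by Henderson's rules, with Mendelian-sampling
variances from parental inbreeding (Meuwissen–Luo recursion) when
requested, and is property-tested against the dense inverse of the tabular
A.  The completeness index is the harmonic mean of the parents'
fraction-of-known-ancestors completeness over a configurable depth
(default 5; reported alongside, since published completeness values rarely
state their depth), and generation counts report both the longest ancestor
path and complete-generation equivalents.  Editing drops cells of modelled
class effects below 2 records (iterated to a fixed point, hence
idempotent), then whole environmental groups under the level/record
thresholds (6 levels / 6,000 records for test-day data; 5 / 300 for
single-record data; scaled down proportionally in the desk-scale analysis
scripts, as noted there).

## Numerical choices and degenerate inputs

Covariate scaling is min–max to [−1, 1] (the standard random-regression
convention); the Legendre basis is plain (unnormalized), so that order-0/1
terms are literally 1 and x and variance components keep their scale.
Quantile class boundaries send ties to the lower class.  Constant
covariates, non-PSD G₀ inputs, rank-deficient fixed-effect blocks, cyclic
pedigrees, null selection indices and disjoint EBV sets raise errors (or
warn and clamp where the quantity has a defined limit, e.g. negative
quadratic forms under a non-PSD G₀).  Accuracy is clamped to [0, 1] with a
flag when PEV exceeds the sire variance.

## Known limitations

Single-trait chains only; step-1 uncertainty is not propagated into step 2
(point-estimate covariates, as in the two-step design); the GLM on ZGZ′
estimates is unweighted by level size; the exact lactation-curve
parameterization of age/month-at-parity classes is simplified to generic
class effects in the synthetic analyses, with the basis machinery (orders
up to 4) available for data that need it.
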