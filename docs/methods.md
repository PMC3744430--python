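# Methods

## The Gaussian C-alpha test

The test is a score test of homogeneity against a central mixture of effect
distributions. Each variant k in a region contributes an effect estimate β̂ₖ
with standard error σ̂ₖ, modelled as β̂ₖ ~ N(μₖ, σ̂ₖ²). Under the null all
μₖ equal a common μ₀; under the alternative the μₖ take a mixture of values
centred at μ₀, which manifests as overdispersion of the β̂ₖ relative to
their sampling variances. For the Gaussian member of the exponential family
the score statistic and its null variance are

    S = Σₖ [(β̂ₖ − μ₀)² − σ̂ₖ²],      c = 2 Σₖ σ̂ₖ⁴,      Z = S/√c.

Each null summand is σ̂ₖ²(χ²₁ − 1), with mean 0 and variance 2σ̂ₖ⁴, so Z has
null mean 0 and variance 1 and is asymptotically standard normal as K grows.
The test is one-tailed: only inflated dispersion (Z large and positive) is
evidence of association. For genetic association μ₀ = 0, since the expected
effect of a minor allele under no association is zero; when a non-zero null
mean is wanted (non-genetic meta-analytic use) the inverse-variance-weighted
mean of the β̂ₖ is the efficient null estimate and is provided as
`inverse_variance_mu0`.

Two properties follow directly and are enforced as tests: Z is invariant to
variant ordering, and to rescaling all (β̂ₖ, σ̂ₖ) by a common factor (S
scales by t², c by t⁴).

The σ̂ₖ entering the statistic are the regression standard errors of the β̂ₖ
— the observed standard deviations of the estimates — not model-derived
quantities. No finite-K correction or nuisance dispersion beyond c = 2Σσ̂⁴ is
applied; permutation is the authoritative calibration in every regime where
that choice could matter.

## Effect estimation

Per-variant estimates are additive-dosage regression coefficients with
intercept and optional covariates: ordinary least squares for quantitative
traits, logistic maximum likelihood (IRLS, 25-iteration cap, deviance
tolerance 1e-8) for binary traits. Dosages are oriented to the minor allele
before fitting, so β̂ₖ is always the effect of the minor allele. Missing
genotypes are handled per-variant (complete-case for that variant only),
preserving sample size elsewhere.

Rare variants make single-variant fits fragile, and the failure modes are
excluded rather than patched:

- zero dosage variance in the analysed subsample, collinearity with
  covariates, or a perfect fit (σ̂ = 0) → the variant is dropped;
- separation in logistic fits (endemic for very rare variants: e.g. every
  carrier a case) → flagged non-converged and dropped;
- a minor-allele-count guard (MAC ≥ 2 by default, configurable) removes
  variants whose estimates could not be stable regardless of fit diagnostics.

The surviving variant set is frozen after the observed-data fit and reused
verbatim in every permutation replicate, so the observed and permuted
statistics always aggregate the same variants. In the rare case that a
permuted replicate degenerates at a kept variant, that variant contributes
its null expectation (β = 0 with the observed σ̂) instead of silently
shrinking K.

For binary traits a one-step estimator — a single Newton step from β = 0,
equivalently the score/information ratio βₖ = gcₖ·(y − p̄)/(w·Σgcₖ²) with
w = p̄(1 − p̄) and σ̂ₖ² = 1/(w·Σgcₖ²) — is available (`one_step=True`). It
agrees with full IRLS to first order for the small effects typical of rare
variants and makes permutation replay a single matrix product, because its
standard errors do not depend on the permuted labels. Default behaviour
remains full IRLS.

## Permutation calibration

The asymptotic normal reference for Z fails when counts are sparse, K is
small, or variants are correlated, so significance is assessed by label
permutation: trait and covariate rows are permuted jointly (preserving their
dependence) against fixed genotypes, the full pipeline is recomputed per
replicate, and

    p = (1 + #{Z_perm ≥ Z_obs}) / (B + 1)

is reported (add-one estimator: never zero, floor 1/(B+1), and valid —
P(p ≤ α) ≤ α under the null for any B). Ties count as exceedances.

For quantitative traits without covariates, the per-permutation regressions
collapse: the trait's total sum of squares is permutation-invariant, so every
variant's slope, residual variance and standard error for all B permutations
come from one K×n by n×B product. The dichotomized case uses the one-step
logistic estimator, whose normalizer c is permutation-invariant. Both batched
engines are validated against the per-replicate loop (same permutations,
identical p) in the test suite. The engines preserve float32 inputs; the
experiment layer uses float32, which perturbs Z by ~1e-3 relative — far below
the spacing of the permutation distribution — while the observed and permuted
statistics go through the identical code path, so exchangeability (hence
validity) is exact regardless of rounding.

## Summary-statistics mode

The statistic needs only (β̂ₖ, σ̂ₖ), so the test can run on published
per-variant summary tables. Without individual-level data no permutation is
possible, and correlated variants inflate the asymptotic test; such results
are flagged `uncalibrated` and should be treated as discovery-only.

## Comparators

**Binomial C-alpha** (binary traits, hard genotypes): models yₖ, the minor
alleles observed in cases out of nₖ total copies at variant k, as
Binomial(nₖ, p₀) under the null, p₀ the case fraction. The statistic is
T = Σₖ[(yₖ − nₖp₀)² − nₖp₀(1−p₀)], normalised by the exact null variance of
each summand, computed by enumeration over yₖ ∈ {0..nₖ} — cheap because
rare-variant nₖ are small, and equal to the central-moment form μ₄ − μ₂²
(both routes are computed and compared to 1e-12 in tests). Singletons
(nₖ = 1) have zero variance term and contribute nothing. No covariates, no
dosages.

**Carrier burden test**: each sample's score is the proportion of non-missing
rare variants at which it carries at least one minor allele (dosage ≥ 0.5 for
imputed data — midpoint rounding of the expected genotype, configurable);
the trait is regressed on the score (linear or logistic) with a two-sided
Wald test. Powerful only under direction-consistent effects, which is
exactly the contrast the experiments exhibit.

## The region and trait simulator

The simulator emulates the calibration study's conditions: diploid samples in
a 30–200 kb gene-sized region, rare polymorphic sites, and a quantitative
trait driven by a mixture of increaser/decreaser rare causal variants.

- **Sites**: count ~ Poisson(θ · length_kb); θ is the expected number of
  polymorphic rare sites per kb.
- **Frequencies**: population MAF per site from the neutral spectrum,
  density ∝ 1/f, on [1/(2n), 0.02]. The support extends one octave above the
  1% analysis ceiling so that realized-MAF windows bounded at 1% experience
  symmetric binomial smearing across that edge, as they would in a real
  region that also carries commoner variants removed by the MAF filter;
  truncating at 1% instead depresses the 0.5–1% window count by ~8%.
- **Genotypes**: Binomial(2, f) independently per sample and site
  (Hardy–Weinberg, no linkage disequilibrium — see limitations).
- **θ calibration**: `calibrate_theta` bisects θ so that the mean simulated
  count of variants in a realized-MAF window matches a target (the null
  study targets 34 variants with 0.2%<MAF<1% in 50 kb at n = 2,000). The
  evaluation draws site MACs as Binomial(2n, f) without materialising
  genotype matrices, which is distribution-identical and fast. Once pinned
  to the 0.2–1% count, the same θ implies ~14.5 variants in the 0.5–1%
  window — an out-of-sample check of the spectrum shape.
- **Trait**: causal variants are accumulated in random order from those with
  MAF < 1% until their summed MAF first reaches 5% (both bounds
  configurable); round(prop_risk · n_causal) of them are trait-increasing. A
  common absolute effect a is solved from the variance decomposition under
  independent Hardy–Weinberg sites, a = √(h² / Σ 2fₖ(1−fₖ)) with total trait
  variance 1 and residual sd √(1−h²); the default h² = 0.006. Equal |a|
  across causal variants is the simplest model consistent with a
  net-effect architecture parameterised by total causal MAF, mixture
  proportion and variance explained. y = Σ signₖ·a·gₖ + ε, ε ~ N(0, 1−h²).
- **Dichotomization**: cases are the upper half of the trait distribution
  (strictly above the median; ties broken at random so case and control
  counts differ by at most one).

What the simulator does **not** reproduce: linkage disequilibrium,
recombination, demography-driven spectra, and case/control ascertainment
beyond median splitting. Type-I-error calibration is insensitive to LD under
permutation (the permutation test is valid conditional on any genotype
configuration), but power under strong LD is not claimed by these
simulations. `sample_region` accepts a `site_sampler` hook so a coalescent
simulator can be plugged in where LD matters.

## Experiments and problem sizes

`type1_experiment` estimates P(p ≤ α) under h² = 0; each replicate simulates
a fresh region and trait, and the same region and permutation assignments are
shared across MAF windows and trait kinds, mirroring one pass over one
dataset. Estimates carry Wilson 95% intervals. The desk-scale profile —
12,000 quantitative and 4,000 dichotomized replicates at B = 1,000 — resolves
the 0.01 level well (granularity of p is 1/1001; the exact null rejection
rate of the add-one test at α = 0.01 is 10/1001 ≈ 0.00999); the 1e-4/1e-5
cells of a 100,000-replicate study are cluster-scale and out of the default
profile. `power_experiment` sweeps the risk/protective mixture grid at h² >
0; rejection uses the one-tailed asymptotic threshold by default (at the
10,000-sample, MAF > 0.5% design where power is evaluated, the permutation
and asymptotic scales agree), with permutation power available via
`power_permutations`. `region_size_experiment` repeats the power sweep over
region lengths at fixed θ, exhibiting dilution by non-causal variants.

## Numerical and design notes

- Strict MAF window inequalities (maf_min < MAF < maf_max) on realized MAF.
- Monomorphic variants get MAF 0 and survive orientation (they are removed
  by filtering, not errors).
- BED regions are 0-based half-open; `chr:start-end` strings 1-based
  inclusive; internal coordinates 0-based half-open.
- Multiallelic VCF records are skipped with a counted warning: rare-variant
  MAF semantics are ambiguous for them.
- Permutation reproducibility: a `PermutationPlan` seed fixes the p-value
  bit-for-bit; experiment replicates draw child streams from a single
  `SeedSequence`.
- Constant burden scores, empty regions after filtering, single-class binary
  traits, and non-finite summary rows raise immediately with the offending
  unit named.

## Known limitations

- No LD in the default simulator (see above).
- The one-step logistic estimator slightly underestimates |β| for large
  effects; it is used only where the effects are small by design (null
  calibration and rare-variant power runs), and full IRLS is the default
  everywhere else.
- Summary-statistics mode cannot be permutation-calibrated by construction.
- The asymptotic p-value is anticonservative for small K because S is a
  weighted centered chi-square sum with positive skewness (≈ 8Σσ̂⁶/c^{3/2} —
  about 0.6 at K = 50); a Kolmogorov–Smirnov test against N(0,1) will detect
  this at a few thousand draws. This is a property of the statistic, not an
  implementation artifact, and is the reason permutation p-values are the
  reporting default.
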