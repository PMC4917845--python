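# Methods

## The model

A twin pair's phenotype vector (y₁, y₂) is bivariate normal with a
structured covariance.  For each sex s, paths a_s, c_s, e_s (cm scale)
give variance V_s = a_s² + c_s² + e_s².  Within-pair covariances follow
from the latent correlations of the classical twin design — additive
genetic values correlate 1.0 in MZ pairs and 0.5 in same-sex DZ pairs,
the shared environment correlates 1.0, the unique environment 0:

| group | covariance |
|---|---|
| MZ (same sex s) | a_s² + c_s² |
| same-sex DZ | ½ a_s² + c_s² |
| opposite-sex DZ | r_gOS · a_m · a_f + c_m · c_f |

r_gOS is the additive-genetic correlation within opposite-sex pairs.
Its no-sex-limitation reference value is 0.5; we parameterize the OS
covariance as r_gOS·a_m·a_f (not ½·r_g·a_m·a_f), so the estimate is
directly comparable with 0.5.  MZ and DZ twins are allowed different
means per sex (DZ twins are known to be slightly taller than MZ twins
in childhood); OS pairs use the DZ means.  The full model therefore has
11 free parameters: six paths, r_gOS, and four zygosity×sex means.

Data are complete pairs, so the −2 log-likelihood is evaluated exactly
from per-group sufficient statistics (n, mean vector, scatter matrix);
a per-pair summation path is retained and tested as an algebraic
identity.  Paths are optimized raw and unbounded (variances are their
squares), avoiding box constraints; r_gOS is kept in [−1, 1] by a tanh
transform.  Optimization is multi-start L-BFGS-B from a Falconer-based
starting point (a² = 2(rMZ − rDZ), c² = 2rDZ − rMZ, e² = 1 − rMZ,
computed from the observed group moments, clipped and renormalized)
plus up to four jittered restarts drawn from a fixed restart seed so
fits are reproducible.

### Submodels and tests

- **saturated** (17 parameters): free mean, variance and within-pair
  covariance per group, with mean and variance equated across co-twins
  in same-sex groups because within-pair order is arbitrary (closed
  form: pooled mean, pooled ML variance, ML covariance).  Comparing the
  ACE model against it tests the equal-environment assumption; across
  age groups the test is Bonferroni-corrected (reject iff p ≤ α/m).
- **equal_sexes** (7): (a, c, e) equated across sexes, r_gOS fixed at 0.5.
- **scale** (9): female paths a common multiple of male paths — equal
  standardized proportions, free total-variance ratio.
- **drop_C** (9) and **drop_A** (8): c = 0 or a = 0 (with a = 0, r_gOS
  is unidentified and fixed).

Nested fits are compared by Δ−2LL against χ²(Δdf).  Note the boundary
caveat: when the true component is exactly zero, the LRT statistic
follows a Chernoff mixture (for dropping both sexes' C:
≈ ¼χ²₀ + ½χ²₁ + ¼χ²₂), making the χ²₂-referenced test conservative
(≈2% rejection at nominal 5%).  The test suite demonstrates this
empirically.

### Confidence intervals

Profile likelihood: the 95% bound for a standardized component is where
the profiled −2LL rises 3.841 (χ²₁ quantile) above the minimum, found
by bracketing and Brent root-finding with full re-optimization of
nuisance parameters at each probe.  Proportions are profiled via a
(log-variance, component-split) reparameterization that stays smooth at
the h² = 0 boundary, where a raw-path constraint gradient would vanish;
intervals are truncated to [0, 1] (and [−1, 1] for r_gOS), and boundary
estimates are reported as 0 with a one-sided interval, never sign-
flipped.  Simulation at 5,000 pairs/group shows ~95% coverage.

## Gene-by-age moderation

Path coefficients become quadratics in centred age x = age − 10 (the
centring is purely numerical conditioning):

    a(x) = a0 + a1·x + a2·x²,  likewise c(x), e(x)

with variance a(x)² + c(x)² + e(x)² and MZ/DZ covariances as above.
The mean structure is a zygosity-specific quadratic in x (6
parameters), giving 15 free parameters per group.  The mean structure
is a reconstruction from the printed degrees-of-freedom arithmetic of
the analyses this package re-implements (9 path + 6 mean = 15 for the
sex-equality comparison; 3×15 − 15 = 30 for three regions; 3 for the
quadratic path terms) — the source methods never write it explicitly,
so this is documented as an inference, not a quotation.

Only same-sex pairs enter (requesting OS moments is a usage error);
exact age is used, not the bin midpoint.  Ages vary continuously, so
the likelihood is evaluated per pair (vectorized).  Because groups
share no parameters unless explicitly equated, multi-group ML
decomposes into independent per-block fits whose −2LL values add;
equating blocks refits one block on the stacked data.  Supported
nested ladders: quadratic → linear (a2 = c2 = e2 = 0, Δdf 3) →
constant (paths and means age-invariant, 5 parameters, which
numerically reproduces the age-pooled homogeneous ACE fit), and
free → equated across groups (Δdf 15 per extra group).

## The synthetic-data generator

The generator is first-class, tested code: it draws the latent A/C/E
variables explicitly (not a direct multivariate-normal sample), so
sex-specific cross-paths in OS pairs are explicit and every downstream
estimator can be checked against generating truth.

What it emulates, with defaults as the stated world:

- **Means/SDs**: the published descriptive table of height by age (1–19),
  sex and region (Europe; North-America and Australia; East-Asia).
- **Zygosity mix**: 39% MZ, 34% SSDZ, 27% OSDZ; sexes 50/50.
- **Component trajectories**: heritability rising from the reported
  age-1 values (0.40 boys / 0.38 girls) to the reported peaks (0.83 at
  14 in boys, 0.76 at 13 in girls), with the unique-environment share
  flat at 0.10 (reported range 0.05–0.14); intermediate ages are a
  smooth interpolation chosen once — the sources report only selected
  values.  Shared environment takes the remainder.
- **Scale**: region family counts sized so paired-measurement totals
  (~132k/30k/18k) match the emulated database at ~2 measurement
  occasions per pair; `repeat_prob = 0.5` with a truncated-geometric
  occasion count reproduces the ~2.1 paired measurements per distinct
  pair seen there.  A and C latents persist across a twin's repeated
  measurements (genes and family environment do not change); E is
  redrawn per occasion.
- **Nuisance structure**: cohort random intercepts (0.5 cm SD), a
  secular birth-year trend (0.1 cm/yr over birth years 1960–2005), an
  optional MZ/DZ mean shift (default 0), optional missing co-twins.
  Exact age is uniform within its one-year bin; birth year is the
  measurement year minus exact age, rounded down.
- **Robustness knobs, off by default**: independent measurement error
  (for equal-environment-violation experiments; otherwise error is
  folded into e) and an approximate assortative-mating effect that
  inflates the DZ/OS genetic correlations by ½·assortative_r —
  documented as approximate, for sensitivity experiments only.

What it does *not* emulate: individual growth-curve dynamics beyond the
shared latents (no within-person autocorrelation of E), gestational age
or birth weight, real cohort heterogeneity in measurement protocol, and
real assortative-mating genetics.  A green recovery test therefore
establishes that the estimators are correct for the stated data-
generating process, not that real-data estimates would be unbiased —
notably, uncorrected assortative mating in real data inflates C at the
expense of A, and self-reported heights inflate E.

## Preprocessing rules

- Age window [0.5, 19.5); one-year bins half-open [k−0.5, k+0.5), a
  partition with no double assignment.
- Outliers: hard plausibility bounds (default 30–250 cm), then iterated
  |z| > 3.5 trimming within age×sex strata until stable.  The source
  procedure was visual histogram inspection removing ~0.3% of
  measurements; z_max = 3.5 is tuned so clean simulated data lose ≲0.3%
  (both the bounds and z_max are configurable).  Strata under 10
  records skip the z-rule with a warning.
- One observation per individual per age group: the record nearest the
  bin centre, ties to the earliest record (the source rule is unstated;
  nearest-to-centre is our declared, deterministic choice).
- Cohorts with fewer than 50 measurements are dropped (inclusive at 50).
- Residualization by OLS with cohort fixed-effect indicators: on birth
  year, exact age and cohort within sex×age strata for the per-age
  (univariate) analyses; on birth year and cohort within sex strata for
  the moderation analyses (age must stay in the data as the moderator).
  Rank-deficient designs fall back to minimum-norm least squares (same
  residuals as dropping collinear columns) with a warning.
- Complete pairs only; group labels from zygosity + sexes; OS pairs
  male-first; MZ pairs with discordant recorded sex are excluded and
  counted in a data-error report.

## Numerical choices and degenerate inputs

- Convergence: L-BFGS-B with ftol 1e−12 / gtol ~1e−7; a fit is flagged
  `converged=False` (best point still returned) if the optimizer does
  not report success.
- A singular expected covariance yields −2LL = +inf (rejected by the
  line search), not an exception.
- Saturated moments for a group with one pair are flagged unidentifiable.
- Reported paths are absolute values (the likelihood depends only on
  squares); standardized components always sum to 1 per sex by
  construction.
- All simulation randomness flows from numpy Generators seeded by the
  caller; pipeline stages draw from streams spawned from one global
  seed, and optimizer restarts use a fixed internal seed, so reruns are
  byte-identical.

## Known limitations

- Dominance (ADE) models are out of scope: D cannot be estimated
  jointly with C from twins reared together.
- No assortative-mating-corrected estimation (no parental phenotypes);
  the generator's assortative knob exists only to probe the bias.
- The moderation mean structure is a df-based reconstruction (above).
- Profile CIs are implemented for the full sex-limitation fit, not for
  submodels.
- Boundary truths (zero components) make χ²-referenced LRTs
  conservative; see the boundary-mixture discussion above.
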