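# Methods

## The model

`gxetwin` estimates how measured environmental variables moderate the
additive-genetic variance of an ordinal questionnaire trait, using twin data.
It combines three layers in a single Bayesian model.

**Biometric layer.** For twin *j* in family *i*, the latent trait is
decomposed as A + (C) + E with the usual twin identification: the
additive-genetic factors of a pair correlate 1 for monozygotic (MZ) and 0.5
for dizygotic (DZ) twins, the common-environment component C is perfectly
shared, and E is independent across twins.  Gene-environment interaction
enters as a log-linear moderation of the additive-genetic variance,

    sigma2_A(i,j) = exp(beta0_A + beta1_A' E_ij),

so `exp(beta0_A)` is the A variance at the average environment (environment
scores are standardised) and each slope in `beta1_A` acts multiplicatively
per SD of its moderator.  Each twin's A factor is a standard bivariate
normal (correlation 1 or 0.5) scaled by `exp((beta0_A + beta1_A'E_ij)/2)`;
this reproduces the per-twin variance formula exactly and gives the
cross-twin A covariance `r * sqrt(sigma2_A(E_1) * sigma2_A(E_2))`.  For
likelihood evaluation the A and C factors are integrated out analytically:
given the structural parameters, a pair's latent traits are bivariate normal
with these moments.

**Means layer.** Because moderators may correlate with the trait and within
pairs, each twin's latent mean includes own-environment and co-twin-
environment regression effects (`beta_m`, `beta_mc`), estimated separately
for MZ and DZ families.  This regresses trait-environment covariance —
including gene-environment correlation — out of the mean structure, so
variance moderation is not confounded with mean effects.  The strength of
any gene-environment correlation is deliberately not quantified.

**Measurement layer.** Item responses follow a logistic graded response
model: `P(X_j >= k | theta) = logistic(a_j (theta - b_{j,k-1}))` with
per-item discrimination `a_j > 0` and ordered thresholds.  The variance
decomposition operates on the latent `theta`, not on sum scores.  This is
the point of the integrated approach: sum scores of items whose thresholds
bunch in one tail carry measurement error that varies with trait level,
their distribution is skewed, and a moderated twin model applied to them can
report interaction where none exists.  `spurious_gxe_benchmark` reproduces
this contrast on identical synthetic data.

**Identification.** The latent metric is carried by the item parameters: the
product of discriminations is fixed to 1 (the last log-discrimination is the
negative sum of the others) and the means-model intercept is fixed at 0;
thresholds are otherwise free, so the location that would conventionally be
absorbed by a free intercept lives in the thresholds.  The phenotypic
variance itself is freely estimated (it is not constrained to 1), matching
how the reported tables quote unstandardised variances.  The moderation
slopes and heritability are invariant to the metric anchoring; variance
intercepts are reported on the anchored scale.

## Estimation

Sampling is adaptive Metropolis-within-Gibbs (all proposal scales are tuned
toward 0.44 acceptance during warmup and frozen afterwards):

* latent traits: element-wise random-walk Metropolis against the graded-
  response likelihood and the conditional normal implied by the co-twin,
  vectorised over families and repeated `theta_repeats` (default 2) times
  per iteration — the A/E split is informed by the theta configuration, so
  extra traffic here buys structural mixing;
* item thresholds and log-discriminations: scalar random-walk Metropolis
  (threshold proposals violating the within-item ordering are rejected);
* means coefficients: exact conjugate Gibbs draw — given the pair
  covariances the traits are linear-Gaussian in all own/co-twin effects;
* variance intercepts and moderation slopes: scalar random-walk Metropolis
  on the marginal bivariate-normal pair likelihood;
* a global metric move that rescales theta and the means coefficients by a
  common factor and shifts all log-variance intercepts by twice its log
  (the twin likelihood cancels analytically against the Jacobian, so
  acceptance is governed by the item likelihood, which is what carries the
  scale information);
* variance-exchange moves (A<->E, and A<->C, C<->E in ACE fits) that move
  variance between two components while keeping the total fixed, with the
  exact Jacobian — these traverse the A/C/E ridge that coordinate-wise
  walks cross slowly.

Moderation slopes are held at zero for the first 40% of warmup so the
variance intercepts settle at the well-identified no-moderation posterior
before the slope dimensions open; without this, free slopes over a
collapsed A component destabilise warmup.  Variance intercepts are
initialised from method-of-moments estimates (the MZ/DZ cross-twin
covariance contrast of raw-score proxies), thresholds from pooled category
frequencies.

**Priors.** Normal(0, 5^2) on means and moderation coefficients and on
thresholds (order-constrained); LogNormal(0, 1) on discriminations;
Normal(0, 2^2) on the log-variance intercepts.  The last choice deserves a
note: a very diffuse prior on a *log* variance concentrates enormous mass on
the degenerate region "variance ~ 0" (every unit of prior sd below ~-4 is
another decade of near-zero variances).  When a component is weakly
identified — the A variance in an ACE model with heritability ~0.16 at
~1000 pairs has a likelihood that is nearly flat below about half its true
value — that mass pulls the posterior into collapse, and the moderation
slopes, which are unidentified at sigma2_A = 0, go prior-diffuse.  A sd of
2 still spans variances from 0.02x to 55x the data scale and leaves the
well-identified AE fits unchanged, while keeping the weakly identified ACE
posterior on the ridge the data actually support.  All prior scales are
overridable (`MCMCConfig`, or the `priors:` block of a fit config).

**Diagnostics.** With two or more chains, split-R-hat and effective sample
size (via `arviz`) are computed for every structural parameter; R-hat > 1.1
or ESS < 200 marks the fit non-converged, recorded in `warnings` and in the
CLI manifest — flagged, never silently dropped.  Point estimates default to
the posterior mean; median and kernel-density mode are available.  The 95%
HPD interval is the shortest contiguous window containing `ceil(0.95 n)`
sorted draws, ties broken toward the smallest lower bound; it equals an
exhaustive window scan by construction and is verified against one in the
tests.

**Variable selection** follows the two-stage workflow: candidate moderators
are fitted in per-category models (each with their main effects), a variable
is kept when its slope's 95% HPD excludes zero, and the final model refits
all selected variables jointly.  Final-model HPDs are reporting, not
re-selection.

## The synthetic-data generator

Real data of this design (1085 pairs of 16-year-old twins, 419 MZ + 666 DZ,
two 9-item 7-category SWAN subscales, self-reported environmental scales)
are access-restricted, so the generator emulates their statistical anatomy;
the shipped scenarios use the published point estimates as generating
values:

* `hyperactivity_scenario`: AE, A = 0.17 and E = 0.23 at the average
  environment (total 0.40, h^2 = 0.43), three moderators with slopes 0.15,
  0.24, 0.22;
* `inattentiveness_scenario`: ACE, A = 0.09, C = 0.07, E = 0.38 (total
  0.54, h^2 = 0.16), five moderators with slopes 0.24, 0.34, -0.58, 0.40,
  0.27;
* family-level missingness 95/2/1/2% (complete / one item / two-to-eight
  items / one twin's whole subscale), items blanked uniformly at random;
* environments standard normal with within-pair correlation 0.40, mutually
  independent; own/co-twin mean effects 0.10/0.05 per SD for all variables
  and both zygosities.  The within-pair correlation, the mean effects, the
  item discriminations (spread 0.7-1.3 around 1, product 1) and thresholds
  (evenly spanning about +/-1.4 latent units with small per-item shifts)
  are not printed in the source tables; they were fixed once at values
  typical for self-report scales of this length and are stated here rather
  than tuned.
* `skewed_null_scenario`: no true moderation, a strong own-environment mean
  effect (0.40/SD), and a ceiling-profile item set (all thresholds well
  below the trait mean) whose sum scores are left-skewed (skewness about
  -0.85 at default severity) — the configuration in which sum-score
  moderation analysis manufactures spurious interaction.

Environments are exogenous; trait-environment correlation arises only
through the means layer, matching what the analysis model can remove.  An
optional `rge_loading` hook tilts an environment toward the genetic factor
for robustness probes (off by default).  The generator does not simulate
selection effects, perinatal exclusions, rater disagreement, sex-limitation
structure, or cross-environment correlations; recovery results on it
therefore demonstrate internal consistency of model and sampler under the
model's own assumptions, not robustness to the ways real cohort data violate
them.

## Problem sizes and reproduction

The test suite runs recovery checks at a CI scale chosen to keep the whole
suite within a routine budget: 150 pairs with two short chains for
containment checks, 20 replicates of 150-200 pairs with a single chain for
the null-calibration and skewness-contrast suites.  `scripts/acceptance.py`
re-runs the two headline recovery analyses at the full study scale
(419 + 666 pairs; 2 chains, 800 warmup + 700 retained draws thinned by 2)
over replicated data/chain seeds, and reports for each target the median
across replicates of the per-fit posterior mean of the slope.  The median is
used because in a minority of ACE replicates the weakly identified A
component sits in its collapsed posterior region and the slope magnitude
inflates (the slope rides on 1/sigma2_A); the median is insensitive to
those replicates while involving no reference to the published values.
Residual upward bias of the recovered slope magnitudes of order 10-15%
remains at these generating conditions; it shrinks with sample size and
with the identifiability of A, and the generating value lies inside the
fitted 95% HPD in the overwhelming majority of replicates.

## Known limitations

* Scalar random-walk updates keep the implementation dependency-light but
  give modest effective sample sizes on the variance intercepts (~50-150
  per 1400 retained draws at full scale); runs that matter should use two
  or more chains and heed the convergence flags.
* The ACE decomposition at h^2 ~ 0.16 and ~1000 pairs is intrinsically
  weakly identified; posteriors for beta0_A are asymmetric and slope
  magnitudes correlate with the A-variance estimate.  This is a property of
  the design, not of the estimator.
* Missingness is treated as ignorable given the latent trait (the observed
  pattern is family-clustered and small).
* One trait at a time; multi-rater and multidimensional measurement, ADE
  decompositions, sex-limitation and explicit gene-environment correlation
  estimation are out of scope.
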