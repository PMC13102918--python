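# Methods

This note documents the models implemented in `twinmiss`, the choices
made where the design was genuinely open, and what the package's
simulation-based tests do and do not establish.

## The classical twin design

A trait measured on both members of MZ and DZ twin pairs identifies
three variance components under the standard assumptions (equal
environments across zygosity, random mating, no dominance or epistasis,
no gene–environment interaction):

- **A** — additive genetic variance, correlated 1 within MZ pairs and 0.5
  within DZ pairs (DZ twins share on average half of the segregating
  DNA; the 0.5 is a fixed model constant, not an estimate);
- **C** — shared environment, correlated 1 within every pair;
- **E** — unique environment, uncorrelated between twins; it absorbs
  measurement error.

Standardised shares a², c², e² sum to 1 and imply the Falconer
correlations rMZ = a² + c², rDZ = ½a² + c².  The package fits the full
ACE model and its AE/CE/E restrictions; an ADE (dominance) model is
deliberately out of scope.

## Likelihoods

**Continuous traits.**  Pairs are bivariate normal with a common mean μ,
total variance σ², and covariance (a²+c²) or (½a²+c²) times σ² by
zygosity.  Pairs with one absent member contribute the univariate
N(μ, σ²) likelihood of the observed twin (full-information maximum
likelihood), so incomplete pairs are retained rather than dropped.

**Binary traits (liability-threshold model).**  A binary outcome (1 =
data missing) is a dichotomised latent standard-normal liability:
P(y = 1) = 1 − Φ(τ).  The liability variance is fixed at 1 and the
threshold absorbs location — the standard identifiability constraint —
so a threshold model has one fewer free-parameter class than its
continuous analogue.  Pair outcomes are multinomial over the 2×2 table
with cell probabilities given by bivariate-normal orthant integrals at
the zygosity's liability correlation; the correlation inferred from a
2×2 table in the saturated model is the tetrachoric correlation.
Incomplete pairs contribute a marginal Bernoulli term.

Orthant probabilities use the Drezner–Wesolowsky/Genz Gauss–Legendre
algorithm (`twinmiss._bvn`), vectorised, with absolute error below
1e-10 across the correlation range — integration error is negligible
relative to the 1e-3-level oracle tolerances used in testing.

**Saturated models.**  The unconstrained reference estimates a mean and
variance (or threshold) per zygosity-by-twin-order cell plus a
correlation per zygosity: 10 free parameters continuous, 6 threshold.
Equality constraints across twin order and then across zygosity produce
the nested assumption tests; fixing a correlation at zero produces the
twin-correlation significance test.  Twin order is the data file's
column order and is carried through unchanged, since the order-equality
assumption is only meaningful for a stable ordering.

## Estimation and numerics

- Continuous ACE-family models are parameterised by unconstrained path
  coefficients (the reported shares are squared paths normalised by the
  total variance), which keeps every component non-negative without
  boundary penalties.  Threshold models optimise (τ, paths) with
  e² = 1 − a² − c² kept strictly positive by a hard wall plus a log-barrier
  of weight 1e-9 — small enough to leave interior optima unchanged at
  any reported precision.
- Optimisation is Nelder–Mead from five deterministic starts (a
  moment-based Falconer start plus near-corners and the centroid of the
  share simplex), followed by a tighter polish from the best point;
  likelihood ties below 1e-8 break toward smaller a².  Convergence
  tolerances: simplex 1e-10 in parameters, 1e-12 in function value.
  The unconstrained saturated continuous model with complete pairs is
  solved in closed form (sample means, maximum-likelihood variances,
  Pearson correlations), as is the E model (pooled mean/variance or
  threshold) — in these cases the sample statistics *are* the MLE.
- Degenerate 2×2 tables (fewer than three occupied cells) produce a
  boundary warning and a tetrachoric correlation clamped at ±0.999
  rather than an error.
- Profile-likelihood 95% CIs collect parameter values whose
  constrained-refit −2LL lies within 3.841 (χ²₁) of the minimum, located
  by bisection to 1e-4 and truncated to the admissible range; a lower
  bound of exactly 0 (or an upper bound of 1) indicates truncation.
- Likelihood-ratio statistics are clipped at zero for reporting (tiny
  negative values are optimiser noise); the raw value is retained.
  Boundary nulls (a variance forced to 0) are referred to the plain χ²₁
  distribution, matching common twin-modelling reporting; the ½χ²₀+½χ²₁
  mixture alternative would make these tests conservative, and the
  calibration tests confirm the conservative direction empirically.

## Model selection and multiple testing

The best-fitting model is the non-significant nested model (LRT vs ACE,
α = 0.05) with the lowest AIC; ACE itself is always a candidate.  AIC
uses fixed per-model parameter counts (continuous ACE/AE/CE/E =
5/4/4/3; threshold = 3/2/2/1), and ties within 1e-8 go to the model
with fewer parameters, then alphabetically.  The significance of a
retained A or C component is a df-1 LRT of the selected model against
E-only, at a Bonferroni threshold 0.05/n_tests — n_tests defaults to 8
for the experiment-level family (two components in each of four models)
and 6 for the trial-level family.

## Preprocessing

Trial-availability counts cluster at the ceiling (left skew).  They are
transformed by y = x^p with the quadratic power p = 2 first; if the
adjusted Fisher–Pearson skewness still reaches 0.3 in magnitude, powers
1.5, 2.5, 3 are tried in that order, and failure to reach the target is
an explicit error carrying the best attempt.  The accepted transform is
standardised to mean 0, sd 1 using the pooled (both zygosities) mean and
sample sd, so the equality-of-moments assumption tests remain
meaningful across zygosity.  Standardised shares are invariant to this
affine scaling.  Inter-rater agreement is summarised by Cohen's kappa
(point estimate and observed agreement only; no kappa variance
estimation).

## Cross-trait correlations

Phenotypic correlations between two missingness scores are Pearson
correlations over individuals.  Because twins are clustered, CIs and
p-values come from a cluster bootstrap resampling whole pairs (2000
resamples by default, seeded).  Cross-twin cross-trait correlations use
the double-entry estimator (both twin orderings stacked), which is
exactly symmetric in twin order; the order-symmetric 4-variate ML
estimate serves as a test oracle only.

## The simulator and what the tests show

`twinmiss.simulate` generates data from the same generative family the
models assume: per-pair latent A/C/E components with the DZ genetic
correlation fixed at 0.5, continuous traits as their weighted sum,
binary traits by thresholding a unit-variance liability at
τ = Φ⁻¹(1 − prevalence).  Default study conditions mirror the analysed
sample: 165 MZ + 132 DZ pairs, composite missingness prevalence 39.6%,
and generating shares equal to the published best-fitting estimates.
Randomness uses one master seed with per-pair substreams
(`SeedSequence.spawn`), so enlarging a sample extends it without
reshuffling existing pairs.  Two-trait data couple only the E
components, which caps the achievable within-person correlation at
√(e²_X·e²_Y) and makes cross-twin cross-trait correlations exactly zero
by construction.

Passing recovery tests therefore establish that the estimators are
correct and essentially unbiased *under the assumed generative model* at
the study's sample sizes.  They cannot establish robustness to
violations real data may carry: non-normal liabilities, sex-limitation
or birth-order effects, informatively missing co-twins (the simulator
blanks values completely at random), or assortative mating.

Problem sizes used in the checks: parameter recovery runs 200 replicates
per condition at the study's sample sizes; oracle-equivalence checks use
30-pair datasets against a 0.005-step share grid; calibration uses 500
replicates (null p-value uniformity) and 50 datasets (CI/LRT duality,
with up to 2 borderline disagreements tolerated).

## Known limitations

- Single-threshold binary model only; ordinal (multi-threshold)
  liability models are not implemented.
- No multivariate (Cholesky) decomposition, no covariates inside the
  twin model, no sex-limitation or dominance models.
- Kappa confidence intervals are not computed.
- The composite missingness code treats an absent per-experiment code as
  missing data (1), on the reading that "did not provide valid data"
  covers non-participation.
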