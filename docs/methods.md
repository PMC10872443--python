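# Methods

This note documents the statistical models implemented in `voxelrel`, the
assumptions they make, the synthetic-data conditions under which they are
tested, and the numerical choices that were genuinely open.

## The measurement model

The unit of analysis is a voxel-level BOLD contrast value (e.g., fearful
minus neutral faces) observed for participant *j* at monthly session *i*
in voxel *k* of an anatomical parcel. The package decomposes its variance
with the Gaussian multilevel model

```
y_ijk = β0 + β_i + λ_j + π_jk + ε_ijk
λ_j  ~ N(0, σλ²)      participant mean (trait-like signal)
π_jk ~ N(0, σπ²)      participant-session mean (state-like signal)
ε_ijk ~ N(0, σε²)     voxel error
```

with fixed session effects β_i (group means per session are always
conditioned out, since task habituation induces real session trends).
From the components:

* **Test-retest ICC** (two-level model per pair of adjacent sessions, the
  participant-session panel of parcel means as data):
  `ICC_pair = σπ² / (σπ² + σε²)`, the ICC(3,1) "consistent agreement"
  coefficient. Here the random intercept is the participant, so σπ² plays
  the role of between-person variance within a pair.
* **Internal consistency** (three-level model over all voxels and
  sessions): `ICC_within = σπ² / (σλ² + σπ² + σε²)` — the share of
  variance carried by participant-session means, i.e., how coherently the
  voxels of a parcel move together within a single scan. Reported as the
  raw share, not divided by the item count, which is deliberately
  conservative for parcels with hundreds of voxels.
* **Multilevel alpha**: `α = σπ² / (σλ² + σπ² + σε²/k)`, the
  generalizability-theory analogue of Cronbach's alpha with k items
  (voxels). `k = 1` reduces to `ICC_within`; `k → ∞` drives the error term
  to zero.

Adjacent session pairs are overlapping — (1,2), (2,3), …, (S−1,S) — with a
disjoint option. Pairwise ICC posteriors are logit-transformed (draws
clamped to [1e−6, 1−1e−6]) and their medians and SDs pooled with a
normal–normal hierarchical meta-analysis, `d_i ~ N(μ, √(τ² + SE_i²))`; the
inverse-logit of the μ posterior (median, central 95% interval) is the
pooled test-retest reliability. With τ fixed at 0 the model collapses to
the closed-form inverse-variance weighted mean, which serves as a test
oracle.

### Estimation backends

Balanced designs admit an exact restricted-likelihood factorization into
independent scaled-chi-square sufficient statistics (between-participant,
participant×session interaction, and within-cell sums of squares), with
the fixed effects integrated out by the REML projection. The default
`mcmc` backend samples the variance components from this restricted
posterior with affine-invariant ensemble MCMC (emcee) under
half-Student-t(3, 2.5·sd(y)) priors on component SDs; because the
likelihood is three numbers, a fit takes ~0.1 s. A split-R̂-style
diagnostic over walker groups is recorded and a warning is emitted above
1.05. The `reml` backend returns the classical mean-squares estimators
(negative components truncated at zero); on balanced data the two agree
within 0.05 and the REML/ANOVA route doubles as the independent oracle
(additionally cross-checked against `pingouin.intraclass_corr` in tests).

Unbalanced voxel panels are rejected by the three-level fit rather than
silently reweighted; participants missing a session are dropped from that
pair in the two-level fit.

## Consistency regression and model comparison

Parcel-level internal-consistency estimates (clamped into (0,1) by 1e−4)
are regressed on parcel size, residual smoothness, and anatomy class
(cortex / subcortex / control) with a logit-link beta regression
(statsmodels `BetaModel`). Two specifications:

* *unconstrained*: cubic B-spline bases (fixed df 4, explicit boundary
  knots from the observed range) in size and smoothness, fully separate
  per anatomy class;
* *constrained*: one linear size slope plus anatomy intercepts.

Fixed-df splines were chosen over penalized smooths for determinism; the
anatomy term is a fixed intercept rather than a random intercept because
three groups cannot support a stable variance estimate (a random-intercept
form would be weakly identified).

Predictive comparison uses leave-one-out ELPD. Exact refits are the
default for n ≤ 600; beyond that (or on request) a Pareto-smoothed
importance-sampling approximation draws from a Laplace approximation of
the parameter posterior (`arviz.psislw`). ΔELPD = ELPD(unconstrained) −
ELPD(constrained), positive favoring the unconstrained model, with the SE
from pointwise differences; models are declared non-equivalent only when
|ΔELPD| > 2·SE, and the constrained model is retained otherwise. Note that
with ~14–24 records in the smaller anatomy classes the unconstrained model
is nearly saturated there, so under a constrained truth exact LOO
typically produces a large negative ΔELPD with a comparably large SE; the
decision *label* (equivalent vs. non-equivalent) fluctuates across
realizations while the retained model is stably the constrained one. The
replicate tests therefore assert retention, not the label.

## Longitudinal within-person inference

Monthly predictors (negative/positive affect scores, two-week mean sleep
duration, episodic stress sum scores, chronic stress maxima) are
decomposed as `x = grand_mean + x_b + x_w` with `x_w` the deviation from
the person mean and `x_b` the person mean centered at the mean of person
means; the reconstruction is exact and the components are orthogonal on
balanced panels. Sleep aggregation uses 24-hour windows from 19:00 to
19:00 ending on the scan date, sums event–window intersections (naps
included, wake gaps excluded, boundary-spanning events split), and treats
windows with no overlapping event as unobserved; fewer than 7 of 14
observed windows yields a missing sentinel (threshold configurable —
a convention, as is the "no event ⇒ unobserved" reading of gaps in the
event stream). Stress scoring: episodic score is the sum of severities on
the 1–5 half-point grid (zero when no events), chronic score the maximum
ongoing-domain severity.

The group-level model for one outcome series is a random-intercept linear
mixed model `y ~ 1 + time + x_b + x_w` (time in months since first scan),
fit by REML. The implementation profiles the restricted likelihood over
the variance ratio ρ = τ²/σ² in closed form (block whitening
ỹ = y − a·ȳ_cluster with a = 1 − (1+mρ)^(−1/2)), verified against
statsmodels MixedLM to ~1e−5. Inference on the coefficients uses the CR2
cluster-robust (bias-reduced) sandwich estimator on the whitened
regression, clustered by participant, with Bell–McCaffrey Satterthwaite
degrees of freedom; the two-sided p-value is converted to a signed Z. CR2
was chosen as the small-sample default (CR0/CR1 would understate
uncertainty at 30 clusters); the robust covariance guards against
residual autocorrelation the random intercept does not capture.

### Freedman–Lane permutation and cluster FWE

The permutation null for the within-person coefficient residualizes the
outcome on (intercept, time, x_b) under the same random-intercept GLS,
permutes residuals only within participants (identity always row 0 of the
permutation set; random rows de-duplicated; exhaustive enumeration for
tiny designs), reconstructs `Y* = fitted + permuted residuals`, and refits
the full robust pipeline. Two deliberate conventions: (i) the whitening
ratio, CR2 adjustment matrices and Satterthwaite df are held fixed at
their observed-data values across permutations — within-block permutation
commutes with block whitening, so the entire computation runs on the
whitened scale, and the identity row reproduces the observed Z exactly;
(ii) the residualization covariates are time and the between-person
predictor component, the nuisance set of the main model. Wide outcome
matrices run the batched permutation algebra in single precision
(relative error ~1e−7 on Z, far below Monte-Carlo noise).

Whole-brain correction is a max-cluster-extent permutation test: |Z|
volumes are binarized at the two-sided cluster-forming threshold (default
p = .01), decomposed into 6-connectivity components, and an observed
cluster survives only if its extent strictly exceeds the (1−α) quantile
of the permutation distribution of maximum extents. This is a single-
threshold stand-in for multi-threshold equitable clustering schemes: it
preserves the permutation FWE contract (calibration verified empirically)
but is less sensitive to clusters much smaller or larger than the
threshold's sweet spot.

### Parcel posteriors and sign-error selection

The parcel-level model places participant and participant-session random
intercepts over voxel-level rows with the same mean structure. On a
voxel-balanced parcel the voxel dimension collapses exactly onto cell
means plus a within-cell sum of squares, so the posterior (emcee over the
marginalized likelihood, same priors as above) is cheap. Each parcel
yields draws of the within-person slope, its median, and the
sign-agreement probability p_s (fraction of draws sharing the median's
sign). Parcels sorted by p_s descending (ties by parcel id) are selected
while the cumulative product of p_s — the probability of no sign error in
the selection — stays at or above 1 − budget (default budget 5%). The
guarantee `∏ p_s ≥ 1 − budget` over the selected set holds by
construction and is asserted property-style in the tests.

### Power simulation

The design power computation generates standardized outcomes
`y = β·d + λ_j + ε` with a unit-SD within-person predictor deviation d
(the analysis re-centers it, leaving in-sample variance (S−1)/S), random-
intercept share τ² = 0.07 — the trait-variance level characteristic of
these contrasts — and residual variance 1 − τ² − β², for 30 participants
× 10 sessions. Each replicate runs the full REML + CR2 + Satterthwaite
pipeline. An analytic check of this convention (effect δ =
β/√(σ²_resid/(N·S·var(x_w))) ≈ 2.9 against t with ~25 Satterthwaite df)
puts power at ≈ 0.81 for β = .17, which the Monte-Carlo run reproduces;
β = 0 recovers the nominal test size.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the estimators assume:
Gaussian variance components with session fixed effects (default: a weak
linear habituation trend), predictors with separable between/within
variance, actigraphy-like sleep events that span midnight and include
naps, stress events on the severity grid, and integer label volumes for
sphere/extraction geometry. Defaults mirror the motivating design
(N = 30, S = 10; variance mix with a small participant share and moderate
participant-session share, i.e., low test-retest reliability with
moderate internal consistency). Missingness is available only as
missing-completely-at-random cell deletion.

Not emulated: raw BOLD time series, hemodynamics, scanner physics, motion
artifacts, spatially correlated voxel noise within parcels (except where
smoothing is applied explicitly in smoothness tests), heavy-tailed random
effects, and informative missingness. Passing tests therefore demonstrate
correctness of the estimators under their own assumptions — not
robustness to the many ways real fMRI data violate them.

## Numerical choices and conventions

* Sphere placement: membership by voxel-center distance; the equal-volume
  radius `r = (3V/4π)^(1/3)` is grown multiplicatively until the lattice
  count reaches the target; a sphere extending beyond the volume or onto
  foreign labels is a containment failure triggering a fresh center (up to
  `max_tries = 1000`); the final set is trimmed to the exact count by
  distance, ties broken lexicographically, so placement is
  seed-reproducible.
* FWHM: classical Gaussian-autocorrelation estimator,
  `FWHM_a = Δ_a·√(−2 ln 2 / ln(1−ρ_a))` with ρ_a the first-difference
  variance ratio, clamped to 0 when ρ_a ≥ 1 (iid limit); combined value is
  the geometric mean over axes. Mixed Gaussian/exponential ACF estimators
  used by some external tools will read higher on heavy-tailed
  autocorrelation.
* Logit clamping of ICC draws at 1e−6; beta-regression response clamp at
  1e−4.
* Ensemble MCMC: walkers = max(2·dim+2, 12), ≥600 steps, first half
  discarded; seeds derived deterministically from caller seeds.
* REML profile search over log ρ ∈ [−12, 8] with an explicit ρ = 0
  boundary comparison; negative variance components truncated at zero in
  moment estimators.
* Problem sizes: the familywise-error calibration runs 200 null datasets
  on a 24³ grid restricted to a spherical mask of ~3.5k voxels with 500
  permutations each (250 in the test suite); power and type-I checks use
  1000 replicates. These sizes put Monte-Carlo SEs well inside the
  asserted tolerances while keeping a full run in minutes on one core.

## Known limitations

* The cluster correction is a single-threshold extent test, not a
  multi-threshold scheme; sensitivity claims transfer only partially.
* Bayesian machinery samples marginalized balanced-design likelihoods;
  heavily unbalanced panels fall back to pairwise deletion (two-level) or
  are rejected (three-level) rather than being reweighted.
* The beta regression treats internal-consistency estimates as known
  responses; their posterior uncertainty is not propagated into the
  size/smoothness model.
* Real-data ingestion is limited to tidy CSV panels and NIfTI volumes;
  first-level modeling, registration, and preprocessing are out of scope.
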