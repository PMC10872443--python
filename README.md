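# voxelrel

Reliability and longitudinal within-person inference for densely sampled
task-fMRI contrasts.

Dense-sampling ("precision neuroscience") studies scan the same
participants many times — here the motivating design is 30 participants
with 10 monthly sessions of an emotional-faces contrast — and ask two
questions that classic between-person fMRI cannot: how much of a contrast's
variance is stable trait signal versus state-like monthly fluctuation
versus measurement error, and do behavioral states (mood, sleep, stress)
track those monthly fluctuations within a person? `voxelrel` implements
that full analysis chain for researchers working with parcel/voxel contrast
panels, with a synthetic-data module that reproduces the assumed variance
structure so every stage is testable against known ground truth.

## The models

Voxel contrast values follow the three-level decomposition

    y_ijk = β0 + β_i + λ_j + π_jk + ε_ijk,
    λ_j ~ N(0, σλ²),  π_jk ~ N(0, σπ²),  ε_ijk ~ N(0, σε²)

(session fixed effects β_i, participant intercept λ_j,
participant-session intercept π_jk). From the variance components:

* **Test-retest reliability** — per adjacent session pair,
  ICC_pair = σπ²/(σπ² + σε²) (ICC(3,1), the two-level model's participant
  variance share), pooled across pairs on the logit scale with a
  normal–normal meta-analysis whose back-transformed mean is the latent
  reliability.
* **Internal consistency** — ICC_within = σπ²/(σλ² + σπ² + σε²), the
  participant-session variance share across a parcel's voxels, with the
  generalizability-theory alpha α = σπ²/(σλ² + σπ² + σε²/k) as companion.
* **Consistency regression** — parcel-level ICC_within modeled as
  beta-distributed (logit link) in parcel size, residual smoothness
  (FWHM), and anatomy class; a spline-rich and a constrained linear model
  are compared by leave-one-out ELPD with a |ΔELPD| > 2·SE rule.
* **Longitudinal inference** — predictors split into within-person
  (x_w = x − person mean) and between-person (x_b) components; a
  random-intercept model y ~ 1 + time + x_b + x_w fit by REML with CR2
  cluster-robust SEs and Satterthwaite df; Freedman–Lane permutation with
  within-participant shuffling; max-cluster-extent familywise-error
  correction of Z volumes; parcel-level Bayesian posteriors selected so
  the joint probability of a sign error stays below 5%; and a Monte-Carlo
  power analysis of the design.

Estimation backends: seeded ensemble MCMC (emcee on exact balanced-design
restricted likelihoods, half-Student-t priors on SDs) or closed-form
REML/ANOVA. See `docs/methods.md` for assumptions, conventions, and
limitations.

## Worked example

```python
import numpy as np
from voxelrel import (
    VarianceComponents, generate_parcel_voxels, generate_predictor_panel,
    inject_within_effect, fit_internal_consistency, retest_reliability,
    fit_longitudinal_model,
)

# a parcel with little trait variance but clear monthly signal
vc = VarianceComponents(
    grand_mean=0.5, session_effects=tuple(-0.02 * np.arange(10)),
    sigma_lambda2=0.02, sigma_pi2=0.12, sigma_eps2=0.18,
)
panel = generate_parcel_voxels(vc, n_participants=30, n_sessions=10,
                               n_voxels=50, seed=7)
pred = generate_predictor_panel(between_sd=1, within_sd=1,
                                n_participants=30, n_sessions=10, seed=8)
panel = inject_within_effect(panel, pred, beta_within=0.3,
                             beta_between=0.0, beta_time=0.0)

cells = panel.groupby(["parcel", "participant", "session"])["value"].mean().reset_index()
ests, pooled = retest_reliability(cells, seed=1)
within = fit_internal_consistency(panel, seed=2)
fit = fit_longitudinal_model(cells, pred)
print(f"pooled test-retest ICC: {pooled.icc_median:.3f} "
      f"[{pooled.icc_ci[0]:.3f}, {pooled.icc_ci[1]:.3f}]")
print(f"internal consistency:   {within.icc_median:.3f} "
      f"[{within.icc_ci[0]:.3f}, {within.icc_ci[1]:.3f}]")
print(f"beta_within: {fit.params['x_w']:.3f}  (Z = {fit.zvalues['x_w']:.2f}, "
      f"p = {fit.pvalues['x_w']:.2e})")
```

prints

```
pooled test-retest ICC: 0.070 [0.017, 0.209]
internal consistency:   0.535 [0.492, 0.580]
beta_within: 0.304  (Z = 7.47, p = 8.18e-14)
```

— the regime dense-sampling studies report: almost no stable between-person
signal month to month (pooled ICC ≈ 0.07), substantial voxel-level
coherence within a scan (ICC_within ≈ 0.54), and an accurately recovered
within-person effect of the behavioral predictor (truth 0.3).

The same chain runs from the shell:

```bash
voxelrel run-all --seed 42 --out demo_run     # simulate → ICCs → … → report
voxelrel power --seed 1 --out demo_run        # design power only
voxelrel validate --stress-events events.csv  # schema checks (exit 2 on error)
```

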