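# Methods

## Model

`growthtraj` fits polynomial multilevel growth-curve models to repeated
measures. For subject *i* at occasion *j* with age/time *t\_{ij}*:

```
y_ij = Σ_{d=0}^{D} β_d t_c^d  +  x_ij' β_cov  +  Σ_{d=0}^{q-1} u_id t_c^d  +  ε_ij
u_i ~ N(0, G),   ε_ij ~ N(0, σ² / w_ij),   t_c = t − time_center
```

* **Fixed polynomial degree D** ∈ {1, …, 4} (0 = intercept-only is allowed
  for variance-component models). Quartic is the ceiling because raw
  polynomials beyond that are rarely identifiable from cohort sweeps.
* **Random degree** ∈ {0, 1, 2} → q = 1..3 random terms (intercept, slope,
  quadratic), unstructured covariance `G`.
* **Weights** are precision (inverse-variance) weights: the residual
  covariance is `σ²·diag(1/w)`. Survey weights supplied by users are
  interpreted this way; the scale-invariance `(c·w, c·σ²) ↦ same model` is
  tested.
* **Interactions.** One optional interaction variable multiplies every
  polynomial term, giving group-specific trajectories. Continuous
  interaction variables are standardized (mean 0, sd 1, n−1 denominator);
  categorical ones are treatment-coded with the *lowest* level (numeric
  order when every level parses as a number, else lexicographic byte order)
  as reference. Plain covariates enter as main effects only.
* **Missing data.** Rows missing the outcome, the time, any covariate, the
  interaction variable or the weight are excluded before fitting
  (listwise at the row level); subjects contribute whatever complete rows
  they have, which is exactly the ML "use all observed data" treatment of
  outcome missingness. Rows with an observed outcome but missing time are
  kept in the long dataset (they still inform per-occasion description) and
  dropped only at fit time.

## Estimation

`β` and `σ²` are profiled out analytically. Writing `G = σ² Λ Λ'`, the
optimizer works only on the log-Cholesky parameters of the relative factor
`Λ` (log diagonal, free off-diagonal), so `G` is positive semidefinite by
construction, never by projection. The profiled ML deviance is

```
dev_ML(θ)  = Σ_i log|V*_i| + n (log 2πσ̂² + 1),      σ̂² = r²/n
dev_REML(θ) = Σ_i log|V*_i| + log|Σ_i X_i'V*_i⁻¹X_i| + (n−p)(log 2πσ̂²_R + 1)
```

with `V*_i = Z_i Λ Λ' Z_i' + diag(1/w_i)` and `r²` the GLS residual
quadratic form. Subjects with equal cluster sizes are batched into stacked
3-D arrays and factored with vectorized Cholesky decompositions, which keeps
a 500-subject × 5-occasion fit around half a second on one core.

Optimization is L-BFGS-B (numerical gradients, ftol 1e−12, ≤500 iterations,
log-diagonal bounded in [−10, 8]); on an abnormal termination the fit
restarts with Nelder-Mead from both the failed point and the identity
factor. Genuine non-convergence raises a structured error carrying iteration
counts and gradient norms. `V = Var(β̂)` is the inverse GLS information at
the optimum (`σ̂²(ΣX'V*⁻¹X)⁻¹`), verified against a direct recomputation.
`σ̂²` is floored at 1e−12/n so noise-free (exact-fit) inputs return instead
of diverging; such fits and any `G` eigenvalue below `1e−8·max(tr G, 1)` set
`singular=True` with a warning — a boundary fit, not an error.

The restricted log-likelihood is defined as the ML log-likelihood minus
`½ log|Σ X'V⁻¹X|` plus `(p/2) log 2π`, the convention whose maximum equals
the criterion above. REML deviances are not comparable across different
fixed-effect structures and are flagged as such in reports.

## Centering

Raw-age polynomials up to degree 4 are badly conditioned, so the optimizer
always works in a basis centered at the mean modelled age, regardless of the
`time_center` the caller asked for (default: that same mean). Results are
mapped to the requested basis by the exact binomial change-of-basis matrix
`M[k,d] = C(d,k)(c−c₀)^{d−k}` applied blockwise to `β`, `V` and `G`. Because
the optimization itself is identical for every requested center, all
fitted values, predictions, AUCs and contrasts are invariant to `time_center`
to float precision (tested at 1e−8), while the displayed coefficients are
basis-dependent — the familiar situation in polynomial regression. For the
same reason raw coefficient tables are not expected to match other software
that centers differently; predictions are.

## Inference on trajectories

Every reported quantity is a linear contrast `c·β`:

* **Prediction at age t**: `c = [1, t_c, t_c², …]` plus encoded covariate
  and interaction entries. Variance `c'Vc` is the *exact* sampling variance
  of the linear combination, so the "delta method" interval
  `c·β̂ ± 1.959964·√(c'Vc)` involves no approximation beyond normality of β̂.
* **AUC over [a, b]**: weight `w_d = [(b−c₀)^{d+1} − (a−c₀)^{d+1}]/(d+1)`
  per polynomial column; constant columns contribute `value·(b−a)`. The
  integral is analytic, signed (a negative fitted mean subtracts), and
  additive over abutting intervals, all verified against adaptive
  quadrature. Covariates sit at their fit-sample means and categoricals at
  the reference level unless a profile overrides them.
* **Group contrasts**: difference of the two contrast/weight vectors; all
  non-interaction entries cancel, and the full covariance of the shared
  polynomial estimates is respected (the two groupwise SEs do *not*
  subtract in quadrature).
* **Parametric bootstrap** (`β* ~ N(β̂, V)`, percentile interval, seeded
  PCG64) is exposed as an independent check and for users who prefer
  percentile intervals; since contrasts are linear it converges to the Wald
  interval, which the tests exploit.

P-values are two-sided Wald z tests against the standard normal — no
Satterthwaite or Kenward-Roger degrees of freedom. With the cohort sizes
this package targets (hundreds to thousands of subjects) the difference is
negligible; with very few subjects the z-based p-values are anti-
conservative, a documented limitation. The CI multiplier is the exact
Φ⁻¹(0.975) = 1.959964…, not 1.96.

Predictions outside the modelled age range are returned with an
extrapolation warning rather than refused.

## Individual trajectories

BLUPs are the conditional means
`û_i = G Z_i'(Z_i G Z_i' + σ²W_i⁻¹)⁻¹(y_i − X_i β̂)` at the plug-in
parameter estimates; no uncertainty for estimating `G` and `σ²` is
propagated (standard practice, and a known understatement of spread).
Individual curves are drawn over each subject's own observed age range —
subject-level extrapolation is deliberately not offered. Random subsamples
of at most 30 curves (overall, per group, or an explicit id list) use
numpy's seeded PCG64 generator; the seed is echoed in the CLI output. The
shrinkage table compares each BLUP with the subject's own OLS deviation;
the ratio approaches 1 as a subject contributes more occasions.

## Synthetic cohorts

The generator emulates a birth-cohort design: nominal sweep ages with
per-occasion Gaussian age jitter (default sd 0.25 years — children are
never measured exactly on schedule), subject-level polynomial deviations
`u_i ~ N(0, G_true)`, Gaussian residuals, an optional Bernoulli group with
main and per-degree interaction effects, MCAR deletion of occasion
(age, outcome) cell pairs, and monotone dropout with a per-occasion hazard.
All randomness flows from one seed through a single generator.

The default configuration mimics a five-sweep childhood emotional-symptoms
cohort: 500 subjects, nominal ages 3, 5, 7, 11, 14; cubic mean trend
`0.6 + 0.25t − 0.02t² + 0.0006t³` (a score rising from ≈1.2 at age 3 to
≈1.8 at 14 on a 0–10 scale); random intercept/slope/quadratic sds 0.45,
0.07, 0.005 on the raw-age scale with a small negative intercept–slope
covariance; residual sd 0.5. These values are the package's own choices of
a realistic symptom-score cohort; they imply an outcome sd growing from
about 0.7 to 1.5 across childhood, typical of such instruments.

What passing tests on these cohorts do **not** show: robustness to
informative (MNAR) missingness, non-Gaussian outcomes, floor effects of
bounded scores, or measurement-error structure in age — real-data analyses
still need their own diagnostics.

## Numerical conventions

* Missing tokens: `"NA"` (exact, case-sensitive) and empty cells on input;
  always `"NA"` on output; CSV floats use shortest round-trip formatting and
  are re-parsed with a round-trip parser, so write→parse is lossless.
* Quartiles/IQR: linear interpolation between order statistics (numpy
  default), fixed for determinism.
* Rank-deficient fixed designs raise an error naming the collinear columns
  (pivoted QR on unit-normed columns) instead of silently dropping terms.
* Report numbers are formatted with half-even rounding to 2 decimals;
  the templates never recompute, only format.
* Occasion labels default to 1-based integers in column order.

## Problem sizes used in the checks

The statistical acceptance checks run entirely on generated data: 50 small
datasets for the likelihood oracle, 20 balanced layouts for the closed-form
comparison, 10 fits × 2000 bootstrap draws for interval agreement, and
200-replicate recovery studies at the default 500-subject cohort (with and
without 20% MCAR) for bias and coverage — sizes chosen so the whole suite
stays desk-scale while leaving the Monte-Carlo error well below the margins
being asserted.

## Known limitations

* Gaussian outcomes only; no GLMM, no autocorrelated residuals, no crossed
  random effects, no multiple imputation (ML handles outcome missingness
  under MAR; covariate missingness is listwise).
* One interaction variable at a time; higher-order interactions require
  pre-computing a combined variable.
* Individual-level AUC and simultaneous confidence bands are out of scope.
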