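# Methods

## The problem

Two methods measure the same analyte in the same subjects: a
single-biomarker reference assay (call its values `x`) and a multiplex
platform (`y`). Both are noisy, both are "right" on their own calibration
scale, and neither can be treated as ground truth. The package answers
three questions: how are the scales related (regression), how well do the
methods agree once one is mapped onto the other's scale (agreement), and do
both methods support the same epidemiological conclusions (gradients across
risk groups)?

## Errors-in-variables model

Each subject has a true level `t_i`; the methods observe

    x_i = t_i + δ_i,          y_i = α + β t_i + ε_i

with independent errors. λ denotes the ratio of the method-1 (x) to
method-2 (y) error variances at a given true level; internally the
closed-form slope uses δ = 1/λ in the standard parameterisation

    β̂ = [S_yy − δS_xx + √((S_yy − δS_xx)² + 4δ S_xy²)] / (2 S_xy),
    α̂ = ȳ − β̂ x̄,

with central moment sums S_xx, S_yy, S_xy. At λ = 1 this is orthogonal
regression, and the x-on-y fit is exactly the inverse line of the y-on-x
fit — which is why the forward and reverse calibration tables of a method
comparison are consistent with `(−α/β, 1/β)`. An exact line is recovered
for any λ.

### Proportional errors and weighting

Immunoassay noise is proportional to concentration (constant CV), so the
constant-variance fit over a concentration range spanning two orders of
magnitude would be dominated by the highest values. The weighted fit
assigns each pair weight `w_i = 1/d̂_i²`, where

    d̂_i = (x_i + λ β (y_i − α)) / (1 + λ β²)

is the maximum-likelihood estimate of `t_i` given the current line (the
orthogonal projection at error ratio λ). Starting from the unweighted fit,
weights and weighted moment sums are alternated until both |Δβ| < 1e-8 and
|Δα|/median(|y|) < 1e-8 (max 100 iterations; non-convergence returns the
last iterate with `converged=False` and a warning). A non-iterative mode
with line-independent weights `1/((x_i+y_i)/2)²` is available as a
cross-check. The reported residual SD is `√(Σ w_i (y_i−α̂−β̂x_i)² / (n−2))`,
a CV-scale quantity for the `1/d̂²` weights.

Numerical guards: estimated true levels are floored at
`max(1e-12, 1e-3 · median((x+y)/2))` before inversion into weights, so a
pathological intermediate line cannot produce unbounded weights; all-equal
x or y, or zero covariance, raise a degenerate-fit error rather than
returning a vertical or arbitrary line; the weighted fit requires strictly
positive values.

The weighted forward and reverse fits are only approximately inverse
(weights live on different scales when α ≠ 0); the discrepancy is at the
noise level (~1% on default cohorts) and is asserted at that tolerance in
the tests.

### Confidence intervals

Jackknife: leave each pair out, refit, form pseudo-values
`nθ̂ − (n−1)θ̂₍₋ᵢ₎`, and take `θ̂ ± t_{0.975, n−2} · SE(pseudo)`. The result
is invariant to pair ordering; degenerate leave-one-out subsets are skipped
with a warning. The choice of jackknife (rather than an analytic variance)
is a documented convention of this package; coverage is validated by
simulation (below).

### Outliers and censored readings

Method-comparison practice excludes grossly erroneous pairs before
interpreting a fit. Two pre-filters, both off-by-default-able:

* `exclude_below_quantitation` removes pairs with a reading at or below a
  quantitation floor (default 1e-6, the synthetic generator's positivity
  clip). Such readings are censored, not quantitative, and under constant-CV
  weighting they receive enormous weights at the bottom of the range; a few
  of them visibly bias the fit.
* `flag_outliers` removes pairs whose weighted residual from a preliminary
  fit exceeds `threshold` (default 4) leave-one-out SDs. The preliminary
  fit uses the line-independent naive-mean weights so a gross outlier
  cannot capture the very fit used to detect it, and the scale for pair i
  is estimated without pair i, so one outlier cannot mask itself. One refit
  round catches pairs unmasked by the first exclusion. The threshold-4 rule
  is this package's choice; it is configurable.

## Realignment

`realign` maps values through `α + β·v`; `invert_equation` gives the exact
inverse with source/target labels swapped. Realigned values below zero
(possible when α < 0 at the low end of the range) are *not* clipped —
clipping would bias the Bland–Altman mean difference — but a warning lists
the affected positions. Equation composition (A→B then B→C) is supported
but warns, since uncertainty is not propagated.

## Agreement statistics

* **Pearson r**: scipy's product-moment correlation, with explicit errors
  for zero-variance input. Invariant to any positive affine recalibration,
  which is why high r says nothing about absolute agreement.
* **Bland–Altman**: differences `a − b` against means `(a+b)/2`; SD uses
  the n−1 denominator; limits are mean ± 1.96·SD (fixed 1.96, not
  t-based, the standard convention). `scale="auto"` switches to natural
  logs when |Fisher skewness of the raw differences| > 1 (threshold
  configurable); on the log scale the anti-logged mean and limits are
  multiplicative factors (a mean log-difference of 0 maps to factor 1).
* **ICC(A,1)**: two-way subjects × methods decomposition without
  replication,
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`.
  "Two-way mixed" and "two-way random" absolute agreement are numerically
  identical; single-measures is reported because interchangeability of
  single readings is the question. A constant matrix is defined as ICC 1.
  Verified against pingouin's ICC(A,1) to 1e-10.

Note that the sample ICC can exceed the sample r by a few hundredths in
small samples (mean-square mixing across df); the population-level
ordering ICC ≤ r under mean/scale shifts holds in all documented cases and
is what the tests assert.

## Risk-band reclassification

CRP bands use cut points (1, 3) mg/l with labels low/intermediate/high.
Boundary convention (fixed for reproducibility, since values exactly at a
cut are rare but possible): the lowest band is open above (v < 1), the
highest open below (v > 3), so both cut values fall in the middle band.
Cross-tabulations keep all bands even when empty. Kappa and concordance
normalize any table by its own grand total, so tables given as printed
percentages (which may sum to 100.1 after rounding) and tables of raw
counts give identical statistics. Weighted kappa (linear/quadratic) is
implemented but not the default.

## Group gradients and the interaction test

Z-scores are `(v − mean)/SD` over the analysis population, after a natural
log for right-skewed analytes (CRP, SAA by default). Adjusted group means
come from ANCOVA — ordinary least squares of z on group indicators plus
covariates — evaluated at the covariate means; the linear trend contrasts
the group means with centered equally spaced integer scores (0, 1, 2, …),
so reversing the group order flips the trend's sign but not its p-value.

With exactly two methods, the group-by-method interaction of a
repeated-measures ANOVA is identical to the between-group F test on the
within-subject difference `d_i = z_a,i − z_b,i`; the package computes it
that way (covariate-adjusted), and the equivalence is verified against a
split-plot mixed ANOVA oracle. If every `d_i` is zero the interaction p is
1 by convention. Note that constructing a "null" by permuting one method's
values within groups makes every group mean of `d` exactly zero — the F
statistic degenerates and p ≈ 1 — so calibration experiments instead use
two independently noisy readings of a shared true value.

## Synthetic cohorts

`default_codam_config` emulates a middle-aged cardiometabolic cohort of
550 subjects with complete paired data on all four analytes:

| analyte  | marginal (reference channel)   | CV ref | CV multiplex | calibration (α, β) |
|----------|--------------------------------|--------|--------------|--------------------|
| CRP      | median 2.6, IQR 1.4–4.5 mg/l   | 0.6%   | 3.0%         | (−0.33, 0.93)      |
| SAA      | median 7.0, IQR 4.0–13.8 mg/l  | 6.1%   | 2.5%         | (0.47, 0.14)       |
| sICAM-1  | mean 350 ± 91 µg/l             | 5.6%   | 2.5%         | (36.01, 0.53)      |
| sVCAM-1  | mean 476 ± 121 µg/l            | 3.1%   | 2.6%         | (77.83, 0.55)      |

True levels are log-normal (median/IQR or mean/SD converted to log-scale
parameters exactly); noise is multiplicative Gaussian, `value·(1+cv·ε)`,
floored at 1e-6 — the constant-CV model the weighted fit assumes. A
glucose-metabolism factor (NGM 52.9%, IGM 22.2%, DM2 24.9%) shifts levels
on the log scale by per-analyte amounts derived from the per-group
medians/means, centered so the population marginal is preserved.
Covariates (age 59.6 ± 7.0 y, 38.7% women, eGFR 95.7 ± 19.0, 27.6% prior
CVD) are drawn independently of the biomarkers. Each analyte, the
covariates, and each group factor draw from deterministic hash-keyed
substreams of the master seed, so adding an analyte never perturbs the
others and the same config + seed is bit-reproducible.

What the generator deliberately does **not** emulate: correlation between
analytes, correlation of covariates with biomarker levels, storage-time
degradation, serum-vs-plasma matrix effects, lot-to-lot variation, or any
nonlinearity in the inter-method relationship. Passing tests therefore
demonstrate the statistical machinery under its stated assumptions, not
robustness to those real-data features. One consequence of the linear
model with a negative intercept (CRP) is that ~1% of subjects have
expected multiplex values below zero, which the positivity floor censors;
the quantitation filter above exists exactly for these.

Under the default CVs and λ = 1, the generating slope of sICAM-1 is
recovered with a small systematic attenuation (~−0.016): its reference
channel is the noisier one (5.6% vs 2.5% CV), so the 1:1 CV assumption is
misspecified for it. This mirrors what the same assumption would do in a
real analysis and is left visible rather than corrected.

## Validation problem sizes

The simulation-based checks use: 200 replicate cohorts of n = 550 for
jackknife CI coverage of the CRP calibration (coverage ≥ 90% asserted);
1000 replicates of 3 × 180 subjects for the interaction test's type-I
error (within ±2 percentage points of 5%); 100 replicates for trend-test
power; 17×17 coefficient grids on ≤ 25-pair instances for the weighted
objective's optimality. These sizes give Monte-Carlo standard errors
comfortably below the asserted margins.

## Known limitations

* No uncertainty propagation from calibration CIs onto realigned values.
* No Passing–Bablok estimator; OLS appears only as an internal diagnostic.
* No second-pass bias correction after realignment (a residual systematic
  difference can persist for an analyte whose inter-method relationship is
  not truly linear; users can inspect the post-realignment Bland–Altman
  mean for this).
* Two methods per analyte only; no multi-rater designs.
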