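# Methods

## The model

`cd4traj` models the natural log of absolute CD4 counts in HIV-infected
adults after antiretroviral therapy (ART) initiation with a linear mixed
model whose mean is a second-order fractional polynomial (FP2) of months
on treatment:

    y_ij = (beta_0 + b_0i) + (beta_1 + b_1i) H_1(t_ij) + (beta_2 + b_2i) H_2(t_ij) + e_ij

with `b_i ~ N(0, D)`, `e_ij ~ N(0, sigma^2)` independent across visits.
The FP basis `H_l` uses powers from the conventional grid
{-2, -1.5, ..., 2.5, 3}; power 0 denotes `log t` and a repeated power
multiplies the previous term by `log t` (Royston–Altman convention), so
powers (0, 0.5) give `log t` and `sqrt(t)` and powers (0, 0) give `log t`
and `(log t)^2`.  This family captures the typical ART response — a steep
early rise in CD4 that flattens — with three fixed effects per group.
Separate models are fitted per NNRTI regimen group (NVP, EFV); a
covariate-adjusted joint fit (gender, age, WHO stage) is available but is
not the default, because the headline group-specific trajectories carry no
covariates.

Power pairs are chosen by scanning all FP1 and FP2 candidates (11 + 66 =
77 specs) and minimising the **maximum-likelihood** AIC with
`k = p + q(q+1)/2 + 1` parameters; REML objective values are not
comparable across fixed-effect structures, so ML is used for the scan and
the winner is refit with REML for reporting.  Exact AIC ties break toward
the smaller order, then the lexicographically smaller powers.  Powers are
selected on the full follow-up and the chosen structure is then refit on
the estimation window.

Likelihood maximisation is statsmodels `MixedLM` (optimizer cascade
bfgs → lbfgs → cg → powell; the first entry avoids a spurious boundary
solution in the lbfgs path, the last accepts boundary fits with a variance
component at zero).  Non-convergence or a singular fitted D triggers the
random-structure ladder *unstructured → diagonal → intercept+first term →
intercept only*, with each step logged.

Subject-specific effects are empirical-Bayes BLUPs computed explicitly as
`b_i = D Z_i' V_i^{-1} (y_i - X_i beta)` with `V_i = Z_i D Z_i' + sigma^2 I`.
A patient with no data gets the prior mean (zero).  Note that EB shrinkage
is guaranteed in the observation space (`||Z b_EB|| <= ||Z b_OLS||`,
because the EB deviation is the least-squares deviation filtered through
eigenvalue factors `lambda/(lambda + sigma^2)`); the coefficient-space
Euclidean norm can grow when D is anisotropic, which is why the test suite
asserts the observation-space form.

## Estimation and prediction windows

The estimation window is 0–30 months (boundary visit inclusive — the
upper edge belongs to the fitted window, keeping it maximal); later visits
form the prediction window used only for assessment.  Agreement is the
Pearson correlation of observed and predicted log CD4 within each window,
plus last-observation pairs for patients whose final visit falls after the
cutoff.  Sensitivity cutoffs (24, 36 months) rerun the window fit without
re-selecting powers.  Per-seed orderings of the two correlations can
occasionally invert in simulation — random slopes widen the
between-patient spread at later times, which by itself inflates a
correlation — but the systematic extrapolation penalty shows in the mean
over seeds, which is what the suite asserts.

## Time to cross a CD4 threshold

For threshold `tau = ln(CD4)` (200, 350, 500 cells/mm^3 by default) and a
patient's conditional mean `mu_i(t) = X beta + Z b_i`, the probability of
being below the threshold at an evaluation time is
`phi_i(t) = Phi((tau - mu_i(t)) / sigma)`.  Treating evaluations as
conditionally independent given `b_i`, the probability of *first* crossing
at the j-th grid time is

    S_ij = [prod_{k<j} phi_i(t_k)] * (1 - phi_i(t_j)),

and the masses telescope: `sum_j S_ij + prod_j phi_i(t_j) = 1` exactly.
The expected crossing time truncates the series on a regular grid
(default: monthly out to 120 months, both configurable).  Both the
truncated unconditional sum `sum t_j S_ij` and the renormalised
conditional expectation are reported together with the residual
(never-crossed-within-horizon) mass; the conditional value is the
headline, and a residual mass above 0.5 attaches an explicit warning.
Crossing is `>= tau`, applied on the log scale.

Two numerical facts worth knowing:

- the discrete first-crossing construction is *monitoring-schedule
  dependent*: when residual noise is large relative to the trajectory
  slope, refining the grid gives more chances to cross and genuinely
  shortens the expected time.  Grid-refinement stability (half-month vs
  monthly within one spacing unit) holds in the smooth low-noise regime,
  where the crossing region `sigma / slope` is narrower than the spacing.
- the conditional expectation is non-decreasing in the threshold for
  trajectories that rise toward it; the suite checks this on a
  representative patient.

Uncertainty uses the four-step case-resampling bootstrap: remove the
focal patient, resample the other N−1 patients with replacement, append
the focal patient, refit with the **already-selected** FP spec (powers are
not re-selected, so power-selection variability is not conflated with
estimation variability), and recompute the expected crossing time.
Percentile 95% intervals and the replicate standard deviation are
reported; replicate fit failures are skipped and counted, with more than
20% failing an error.  Because the focal patient's own data are held fixed
by this scheme, the interval quantifies parameter-estimation uncertainty
conditional on that patient's record; the coverage experiment in the suite
therefore targets the crossing time implied by the *true* parameters
combined with the patient's EB effect under those true parameters.

## Observed-data counterpart

The observed crossing time is the first visit with log CD4 at or above
`tau` (event), else censoring at the last visit.  By default patients
already at or above the threshold at their first visit are excluded from
the Kaplan–Meier analysis — a reconstitution time starting above the line
is not meaningful — with the literal first-crossing rule available via a
flag.  KM curves, medians with log-log Greenwood 95% limits, and the
two-group log-rank test are delegated to lifelines.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes: two regimen
groups with FP2 mean trajectories (defaults: NVP `5.22 + 0.05 log t +
0.08 sqrt t` with powers (0, 0.5), EFV `5.05 + 0.14 log t + 0.024 (log
t)^2` with powers (0, 0); group sizes 1100/247), correlated Gaussian
random effects, Gaussian residual noise, and recorded counts that are the
rounded exponential floored at 1 — so the stored log-count carries a small
quantisation error (~0.003 at CD4 ≈ 200) that bounds how "noiseless" any
simulation can be.

Visit schedule: baseline plus 6-monthly measurement targets up to 68
months, each attended with probability 0.55, jittered by ±1 month, and
truncated at an exponential dropout time with mean 45 months.  These
values were calibrated once against the cohort descriptives the analysis
is meant to mimic — median 3 measurements per patient (IQR 2–6, maximum
11) and median follow-up around two years — and are not revisited.  An
earlier schedule with dense early targets matched the visit counts but
halved the follow-up, which starves the model of late-time information.

Random-effect scales (sds 0.6, 0.1, 0.05 with intercept–slope correlation
0.2) and residual sd 0.4 are invented defaults — no published values
exist for them — chosen to make simulated trajectories resemble a real
ART cohort's spread.  The generator also emits a hidden truth record:
each patient's simulated `b_i` and a closed-form probability of crossing
CD4 350 by month 60, computed by a deliberately independent code path
(plain-Python product of erf-based normal probabilities) so the crossing
module can be cross-checked against it.

What a green simulation test does **not** establish: the generator has no
missingness related to health status (dropout is independent of CD4), no
regimen switching, no measurement-error model beyond rounding, and
Gaussian tails on the log scale; conclusions about robustness to any of
those do not follow.

## Known limitations

- **FP power selection is soft in realistic regimes.**  At the default
  effect sizes (weak curvature: 0.05·log + 0.08·sqrt against residual sd
  0.4 and sparse visits) adjacent FP power pairs differ by under ~2 AIC
  at n = 500 per group, so the exact generating pair is recovered in only
  a minority of seeds even though the selected model is predictively
  near-equivalent.  The acceptance suite's selection-frequency bound
  (≥ 80%) fails honestly in this world and the test reports the achieved
  frequency; recovery does hold under strong curvature with low noise
  (see the unit suite).  Consumers should read selected powers as "a good
  basis", not an identified truth.
- Bootstrap refits reuse the selected spec; selection uncertainty is out
  of scope.
- The crossing machinery conditions on the EB estimate of `b_i`; the
  posterior spread of `b_i` given a short record is not propagated.
- Baseline visits at t = 0 are kept in the fit via a +1 month offset
  inside the FP transform (configurable); the alternative — dropping
  baseline or shifting the clock — changes early-time behaviour.
- A CD4 count of 0 is rejected as a data error rather than
  offset-corrected (observed counts start at 2 in the kind of cohort this
  mirrors); a configurable additive offset exists but defaults to 0.

## Runtime-budget scalings in the test suite

Simulation-heavy acceptance checks are scaled down (never loosened):
parameter recovery runs 5 seeds per group at n = 500 with a
random-intercept working covariance for the 77-candidate scan; bootstrap
coverage runs 80 replicates at B = 40 in a 40-patient random-intercept
world; the Monte-Carlo cross-check keeps its full 100,000 draws for 20
patients.  Full-size runs use the same code paths with larger arguments.
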