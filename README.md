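# cd4traj

Model-based prediction of CD4 cell-count trajectories in HIV-infected
adults on antiretroviral therapy (ART), and of the time to cross a
clinically meaningful CD4 threshold.

CD4 counts are the classic biomarker of immune reconstitution under ART.
Clinicians and cohort analysts want two things from sparse, irregular
clinic measurements: an early subject-specific forecast of a patient's
long-term CD4 level, and an estimate of *when* that patient will reach an
eligibility threshold such as 200, 350 or 500 cells/mm³.  `cd4traj`
implements a fractional-polynomial (FP) linear mixed-model pipeline for
exactly this, for two NNRTI regimen groups (nevirapine vs efavirenz):

- **Model.**  log CD4 follows
  `y_ij = (β₀+b₀ᵢ) + (β₁+b₁ᵢ)H₁(t_ij) + (β₂+b₂ᵢ)H₂(t_ij) + ε_ij`
  with `bᵢ ~ N(0, D)`, `ε ~ N(0, σ²)`; the FP basis uses powers from
  {−2, −1.5, …, 3} (power 0 = log t, repeated powers multiply by log t),
  selected by ML-AIC over all 77 FP1/FP2 candidates.
- **Early prediction.**  The model is fitted on an estimation window
  (0–30 months) and predicts each patient's later visits via empirical-
  Bayes BLUPs `b̂ᵢ = D Zᵢᵀ Vᵢ⁻¹ (yᵢ − Xᵢβ̂)`.
- **Threshold crossing.**  With `τ = ln(CD4 threshold)` and
  `φᵢ(t) = Φ((τ − μᵢ(t))/σ)`, the probability of first crossing at the
  j-th evaluation time is `S_ij = [∏_{k<j} φᵢ(t_k)](1 − φᵢ(t_j))`, giving
  the expected crossing time `∑_j t_j S_ij` (truncated at a 120-month
  horizon; conditional and unconditional versions are both reported) and
  cumulative crossing probabilities at any time.  Uncertainty comes from a
  leave-one-out case-resampling bootstrap.
- **Observed counterpart.**  First observed crossings, Kaplan–Meier
  curves, medians with 95% CIs and the log-rank regimen comparison.
- **Synthetic cohorts.**  A seeded generator reproduces the assumed data
  structure (two groups, 6-monthly sparse visits with jitter and dropout,
  median 3 measurements per patient), with a hidden truth record for
  estimator validation.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import numpy as np
from cd4traj import (default_cohort_config, simulate_cohort,
                     apply_inclusion_filters, split_periods, FPSpec,
                     fit_fp_lmm, obs_pred_correlation, Threshold,
                     expected_crossing_time)

cohort, truth = simulate_cohort(default_cohort_config(300, 120), seed=1)
cohort = apply_inclusion_filters(cohort)       # >=2 visits, NVP/EFV, AZT backbone
nvp = cohort.by_regimen()["NVP"]
est, pred = split_periods(nvp, 30.0)           # estimation window 0-30 months

model = fit_fp_lmm(est, FPSpec((0.0, 0.5)), method="reml")
model.window_ = (0.0, 30.0)
print(np.round(model.beta_, 3))
print(round(obs_pred_correlation(model, nvp, "estimation"), 3),
      round(obs_pred_correlation(model, nvp, "prediction"), 3))

pid = est.patient_ids[0]
dist = expected_crossing_time(model, pid, Threshold.from_cd4(350.0))
print(round(dist.expected_time_conditional, 2), round(dist.residual_mass, 3))
```

prints

```
[ 5.266 -0.009  0.113]
0.967 0.807
3.72 0.0
```

i.e. the fitted NVP trajectory is `5.27 − 0.01·log t + 0.11·√t` on the log
scale, observed and predicted log CD4 correlate at 0.967 inside the
estimation window and 0.807 in the later prediction window (extrapolation
degrades agreement, as expected), and the first patient — who starts near
the threshold — is expected to cross 350 cells/mm³ about 3.7 months after
ART start, with essentially no probability of remaining below it over the
120-month horizon.

The same pipeline runs from the shell:

```bash
cd4traj simulate --n-nvp 300 --n-efv 120 --seed 1 --out cohort.csv
cd4traj run-all --input cohort.csv --outdir run1 --seed 1
cd4traj km --input cohort.csv --threshold 200
```

`run-all` writes the AIC selection table, per-group model JSON, observed
vs predicted pairs and correlations, the per-patient crossing-time table
for thresholds 200/350/500, sorted crossing probabilities, KM summaries
and a reproducibility manifest into the output directory.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the whole analysis from scratch on a freshly simulated cohort
(simulate → filter → split → AIC power selection over the full grid →
REML fit → prediction diagnostics → crossing times with a bootstrap CI →
KM comparison), prints a summary of what it computed, and writes the
results JSON to `--out`; intermediate artifacts land next to it under
`acceptance_run/`.
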