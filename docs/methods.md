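# Methods

## The question being modelled

An AI system can estimate gestational age (GA) independently of the
operator's biometry. If a novice's biometry-derived GA disagrees grossly
with the AI estimate, the scan can be flagged before a wrong date is
reported. `fetalqc` reproduces the statistical design of that guardrail
analysis on synthetic cohorts: simulate novice measurement error, define
gross error, calibrate discrepancy cut-points on a tuning split, and report
operating characteristics on a held-out test split, together with the
paired accuracy comparison between the AI model and expert biometry.

No images or videos are involved anywhere: the AI estimator is represented
purely by its error distribution.

## Dating formulas

GA estimation from biometry uses published polynomial formulas, described
entirely by flat coefficient files (term grammar: products of measurements,
optionally log-transformed and powered; `transform` selects GA = poly or
GA = exp(poly)). Shipped formulas:

* **Intergrowth-21st** (HC, FL in mm → GA days):
  ln GA = 3.813 + 0.03243 (ln HC)² + 0.001644 FL ln HC. Default, since the
  emulated study population is predominantly dated this way.
* **Hadlock four-parameter** (BPD, HC, AC, FL in cm → GA weeks):
  GA = 10.85 + 0.060 HC·FL + 0.670 BPD + 0.168 AC.

Internally GA is always days and measurements always millimetres; files
declare native units and the loader converts. Loading validates field
completeness, term syntax, a GA validity range within [98, 300] days, and —
numerically, on a sweep — strict monotonicity in each input. Out-of-range
GA estimates are flagged, never clamped (clamping would distort error
distributions); out-of-range inputs raise, with an optional fractional
`range_slack` for simulation code evaluating noisy measurements.

### Median-fetus inversion

The generator needs biometry consistent with a chosen true GA. The fetus is
parameterised by a single latent age along a reference median trajectory:
the international fetal-growth-standard median equations for BPD/HC/AC/FL,
tabulated at quarter-week steps over 12–40 weeks and extended linearly
beyond 40 weeks with each curve's terminal slope (the published head
medians flatten near term, while the dating polynomials saturate, so latent
ages up to ~46–48 weeks are needed before the formulas reach GA 280–294
days). The tabulated curves are interpolated with monotone PCHIP splines
and the latent age solved by vectorised bisection (tolerance 1e−3 days,
bracket = the trajectory range). Round-trip error
|GA(invert(ga)) − ga| is below 0.001 days across 98–280 days, comfortably
inside the 0.1-day contract.

## Cohort generator

One row per scan. Defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| participants | 5,000 | desk-scale analogue of a multi-thousand cohort |
| visits | 1 + Poisson(0.5), capped at 8 | median 1–2 scans per participant |
| GA distribution | 55% U(98, 195) ∪ 45% U(196, 280) days | late presentation for care |
| shared dating SD | 2.5 days | see below |
| model error | mixture matched to MAE 3.87 / RMSE 5.01 days | published model accuracy |
| expert CV | 0.0433 per structure | calibrated to expert GA RMSE 6.47 days |
| splits | 20% test; remainder 4:1 train:tune | participant-level random split |

**Error decomposition.** Ground truth is itself an earlier estimate, so all
GA estimates of one pregnancy share a Gaussian *dating error* (SD 2.5 days
by default). This is the one free structural parameter — the source moments
do not identify the model–expert error correlation — and it is exposed in
config and varied in sensitivity runs. The model's total error is a
two-component zero-mean Gaussian scale mixture solved in closed form for
the target (MAE, RMSE): with weight w = 0.8 on σ₁, the equations
√(2/π)(wσ₁ + (1−w)σ₂) = MAE and wσ₁² + (1−w)σ₂² = RMSE² reduce to a
quadratic whose discriminant is positive exactly when tails are at least
Gaussian-heavy (MAE ≤ RMSE·√(2/π)); for extremely heavy tails w moves along
a fixed grid toward 1, and infeasible pairs raise. Because a Gaussian
shared term folds into each component in quadrature, the generator draws
the model's independent part from component SDs √(σₖ² − s²), so the
*cohort-level* model error reproduces the calibrated moments exactly —
including the shared component.

**Expert error** is multiplicative lognormal per structure, independent
across the four structures (inter-observer error is quoted in percent).
The common CV is calibrated at the GA level — relative measurement error
propagates nonlinearly through the formulas — by bisection against
simulated expert GA RMSE with fixed inner-seed draws (common random
numbers make the objective smooth and monotone). The frozen default,
0.0433, sits inside the reported 3–6% expert inter-observer band, and the
resulting expert MAE (~4.8 days) emerges close to its published
counterpart without being targeted. Duplicate measurements of each
structure are not simulated separately; the drawn value is read as the
mean of replicates and the CV as the effective CV, since no downstream
statistic uses replicates.

**Splits** are assigned by simple random sampling of participants: test
count = round(0.20·n) (half-up), tuning count = round(remaining/5)
(half-up, floor 1), training the rest; all scans of a participant share the
label.

## Novice error and gross-error labels

"Average absolute relative error a" is implemented as a symmetric uniform
relative error: each measurement is multiplied by 1 + u,
u ~ Uniform(−2a, +2a) independently per structure and scan, so E|u| = a and
the support is exactly [1−2a, 1+2a]. The perturbation applies to the
*expert* measurements (not re-drawn from truth), and the novice shares the
pregnancy's dating reference, so the novice−expert discrepancy isolates
measurement error. A scan is a gross error when |novice GA − expert GA| ≥
the definition (boundary included; base 10 days). Perturbed measurements
are validity-checked against ranges widened by 2a, so perturbations of
in-range values are never rejected; the rare scans that still fall outside
(the expert value was already near a range edge) are flagged unusable,
counted, and excluded downstream.

## Guardrail

The deployed device sees only its own estimate and the operator's biometry,
so the flag statistic is |model GA − novice GA| in days (a config switch
evaluates the model-vs-expert variant instead). Calibration restricts
candidate thresholds to observed positive-scan statistics — a step-function
ROC, no interpolation — and picks, for target s, the largest t with
tuning-set sensitivity ≥ s (equivalently the ⌈s·m⌉-th largest positive
statistic); the flag rule is statistic ≥ t, matching the gross-error
boundary convention. Evaluation reports the 2×2 counts and four
proportions with exact Clopper–Pearson intervals (beta quantiles; closed at
0 and 1), and the AUC with the DeLong variance (Mann–Whitney with ties at
½; placement-value variances; CI on the AUC scale, clipped to [0, 1] —
no logit transform, matching the most common formulation). Degenerate
inputs (a single outcome class, no positives) raise typed errors rather
than returning NaNs.

## Comparison statistics

Paired throughout. SE(MAE) = SD(|e|)/√n; SE(RMSE) by the delta method on
the mean squared error; the RMSE difference uses paired influence values
eₘ²/(2·RMSEₘ) −
eₑ²/(2·RMSEₑ). The MAE difference uses the paired t interval. "Within 10
days" is strict `<`; the two estimators are compared by McNemar's test on
discordant pairs (exact binomial below 25 discordant pairs, else
continuity-corrected chi-square; the switch point is configurable) with a
paired Wald CI for the proportion difference,
SE = √(b + c − (b−c)²/n)/n. The trimester boundary is a parameter, default
196 days (second trimester 98–195, third ≥ 196); scans exactly at the
boundary are third-trimester. A seeded one-scan-per-participant subsample
guards against within-participant correlation.

## Experiments and reproducibility

`run_base_case` chains generate → split → novice(7.5%) → calibrate(tune) →
evaluate(test) plus the comparison report; `run_sensitivity_grid` computes
the test-split AUC over {5, 7.5, 10}% novice error × {7, 10, 14}-day
definitions. All grid cells share one cohort and one set of unit
perturbation draws, scaled per level (common random numbers), so the
grid's monotone structure is testable at moderate n. Degraded model inputs
are emulated by multiplying the model's independent error component by a
scalar factor (default 1.1 when enabled) — an analogue of feeding the model
poorer inputs, not a reproduction of any video-level mechanism. One master
seed is spawned into independent child generators per stage, so changing a
downstream stage never reshuffles an upstream one; a run manifest (config +
seed + version) makes every report reproducible byte-for-byte.

Default problem sizes — 5,000 participants for pipeline runs, 10⁶ draws
for law checks, 2,000 replicates for null-calibration simulations — keep
the full analysis and test suite in the tens-of-seconds range while leaving
Monte-Carlo error well inside the asserted tolerances.

## What the synthetic cohorts do and do not show

The generator matches the *marginal* error moments of the emulated study
and its design (splits, repeat visits, late presentation). It does not
model: site differences, GA-dependent model error, structured novice biases
(systematic over/under-measurement, plane-selection physics), correlation
of errors across a participant's repeat visits beyond the shared dating
term, or any image-level mechanism. Consequently, passing tests validate
the statistical machinery and the qualitative structure of the results
(threshold orderings, grid monotonicity, calibration fidelity) — not the
specific operating characteristics a real device would achieve, which
depend on the true joint error distribution. The guardrail AUC here (~0.85
at base case) is in the right regime but should not be read as an estimate
of any particular system's performance.

## Known limitations

* The shared-dating-error SD is an assumption, not an estimate; results
  involving model–expert error correlation inherit it.
* The uniform novice-error law is a literature-motivated convention; real
  novice error is structured and measurement-specific.
* Expert MAE is emergent (only expert RMSE is calibrated), so it tracks but
  does not exactly equal its published counterpart.
* The Hadlock formula saturates near term; inversion beyond GA ≈ 294 days
  is out of range by design.
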