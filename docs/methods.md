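# Methods

This note documents the models, defaults and numerical choices behind
`dopakin`, and what the simulations do and do not establish about real
data.

## Kinetic model and TAC simulation

Tissue curves follow the irreversible two-tissue compartment model: a free
compartment receives tracer from plasma at `K1` (ml·min⁻¹·ml⁻¹) and clears
at `k2 + k3` (min⁻¹); a trapped compartment is fed irreversibly at `k3`.
The reference region (cerebellum) is the same model with `k3 = 0`. All
activities are treated as decay-corrected, so no physical-decay term is
simulated. `k2 = 0` is admitted as the saturated limit in which the tissue
curve is independent of `k3` — the null case of the sensitivity analysis.

The arterial input is a linear-rise/tri-exponential (Feng-type) curve with
defaults (a1 = 200 kBq·ml⁻¹·min⁻¹; a2 = 6, a3 = 5 kBq·ml⁻¹; eigenvalues
4, 0.12, 0.01 min⁻¹; delay 0.5 min) chosen to give a bolus peak of
~25 kBq·ml⁻¹ at ~0.8 min and late striatal/cerebellar concentrations of a
few kBq·ml⁻¹, the magnitudes typical of a ~150 MBq injection. The input
exists only to drive the simulator; the reference-tissue estimator never
sees it. Default region kinetics are striatum K1 = 0.04, k2 = 0.08,
k3 = 0.02 and cerebellum K1r = 0.04, k2r = 0.08 (plausible order-of-
magnitude values, fully configurable); they yield a reference-Patlak slope
of ~0.016 min⁻¹, in the physiological range of Ki_cer.

Numerics: the instantaneous solution is computed on a uniform 0.01-min
grid by trapezoid-corrected FFT convolution of the input with the
`exp(−(k2+k3)t)` kernel (O(dt²) accurate); the trapped compartment is the
running trapezoid integral of `k3·C_free`. Frame values are exact grid
averages over each frame (differences of the cumulative integral), the
quantity a scanner reports. Tests verify the whole route against an
independent adaptive Runge–Kutta solution of the differential form.

Frame noise is zero-mean Gaussian with SD
`noise_scale·sqrt(max(C, 1e-3)/duration_min)` — the standard
count-statistics weighting assumption for dynamic PET (shorter frames and
hotter voxels are noisier). The default `noise_scale = 0.05` gives ~2%
noise on late cerebellar frames, a clean-ROI regime. No attenuation,
scatter, motion or reconstruction effects are modelled: passing tests show
the estimator and inference chain behave correctly for data that truly
follow the compartment model, not that they are robust to image-level
artefacts.

## Frame schedules

Two presets ship: `study1_26f` (1×30 s, 4×60 s, 3×120 s, 3×180 s,
15×300 s = 26 frames, 94.5 min) and `study2_32f` (8×15 s, 3×60 s,
5×120 s, 16×300 s = 32 frames, 95 min). Schedules are stored in seconds,
validated as contiguous and non-overlapping, and converted to minutes only
inside computations.

## Reference-tissue Patlak estimator

The fit regresses `y = C_tar/C_ref` on `x = ∫C_ref/C_ref` over frames with
mid-time ≥ `t_star`. Choices:

* `t_star` defaults to 24 min. The reversible compartments equilibrate
  with time constant ~1/k2r (12.5 min at defaults), so by 24 min the plot
  is linear to R² > 0.999 while 14 late frames remain on the 32-frame
  schedule. It is configurable and recorded in every fit.
* The x-axis integral uses the step-function (frame-mean) reconstruction,
  which is exact for constant curves and consistent with what frame data
  actually are; its crudeness on the early fast-rise frames is irrelevant
  because only post-`t_star` frames enter the fit.
* OLS is unweighted by default; a frame-duration weighting flag exists.
  On noiseless curves the two agree to <0.5%.
* "Truth" for recovery tests is defined operationally as the fine-grid,
  noiseless, extended-duration (180 min) slope of the same generative
  model, because the reference-tissue slope is not algebraically
  K1·k3/(k2+k3). The 95-min, t* = 24 estimate sits within 1% of that
  asymptote at default kinetics (the residual is genuine finite-window
  transient, not integration error).

SUV is frame activity divided by injected activity per body weight
(1 g = 1 ml convention), evaluated at the frame containing the requested
time.

## Cohort generative model

Per subject, true baseline Ki is `Normal(mu_ki = 0.014,
sigma_between = 0.0015)` min⁻¹, floored at 10⁻⁴. Second-scan truth is

* test–retest arm: `ki1 + Normal(0, sigma_drift)`,
* challenge arm: `ki1 + gamma·(setpoint − ki1) + Normal(0, sigma_drift)`,

with `setpoint = mu_ki` by default, and observed values add per-scan
`Normal(0, sigma_measure)`. The default
`sigma_measure = sigma_between·sqrt(1/0.834 − 1) ≈ 0.00067` min⁻¹ is the
unique value making the large-sample test–retest ICC equal 0.834;
`sigma_drift` defaults to 0 so reliability is attributable to measurement
noise alone. `gamma` defaults to 0.5, a mid-range regulation strength that
produces a challenge-arm baseline-vs-change correlation of ~0.8 — the
qualitative regime of interest — while leaving the test–retest arm's
regression-to-the-mean correlation (~0.3) clearly distinct. Arm sizes
default to 8 test–retest and 12 challenge subjects, the canonical design
the battery calibration also uses. Dose labels are free text (a 4-strong
higher-dose subgroup is labelled for realism) and carry no numeric
semantics; inter-scan intervals emulate a ~2-year rest–rest gap and a
~7-week challenge gap.

This is the *minimal* model with both a real regulation mechanism
(`gamma`) and a regression-to-the-mean mechanism (`sigma_measure`) as
separately tunable causes. It deliberately omits dose–response structure,
arm-level mean shifts, heavy-tailed noise and outliers; conclusions about
those require extending it.

### Percent-change sign convention

Percent change is `(baseline − post)/baseline × 100`: *negative* when the
post value increased. Under this convention active regulation makes the
challenge-arm baseline-vs-percent-change correlation strongly *positive*
(high-baseline subjects decrease). The opposite ("increase") convention
`(post − baseline)/baseline` simply negates every such correlation;
reports carry both labels because the field uses both interchangeably and
the sign of the printed correlation depends on the choice.

## The regression-to-the-mean battery

* **Levene** on change scores (classical mean-centred; Brown–Forsythe
  median centring behind a flag). The all-zero-deviation case returns
  W = 0, p = 1 by convention.
* **Mixed-ANOVA interaction**: for two arms × two scans, the group×change
  interaction F is algebraically the squared pooled two-sample t on change
  scores with df (1, N−2); the implementation uses that identity (robust,
  sphericity trivially satisfied) and is cross-checked in tests against an
  explicit sums-of-squares path and against `pingouin.mixed_anova`.
* **Interaction regression**: OLS of scan 2 on {1, baseline, arm,
  baseline×arm}. Under the generative model the baseline×arm coefficient
  *is* −gamma: exact on noise-free cohorts; on noisy cohorts it is mildly
  attenuated toward zero (errors-in-variables through the observed
  baseline, factor ≈ ICC = 0.834), which is visible but small relative to
  the coefficient's standard error at n = 20, so nominal 95% CIs still
  cover −gamma at ≈ 93%.
* **Correlation comparison**: Fisher r-to-z with the independent-samples
  variance `1/(n1−3) + 1/(n2−3)` by default, because the two arms share no
  subjects. Steiger's pooled-r Z₁* for dependent correlations within one
  sample is available behind `method="steiger_dependent"` (it requires the
  cross-correlation of the two non-shared variables). Exclusions are by
  caller-supplied subject id only — never automatic.

### Calibration

`calibration_sim` simulates complete study pairs (8 + 12) from the cohort
model and measures rejection rates at α = 0.05 (two-tailed throughout).
With `setpoint = mu` the regulation moves no group mean, so the ANOVA
channel stays at the nominal level — in fact drifting slightly below it as
gamma grows, because the challenge arm's change-score variance
(γ²σ²_between added) exceeds the test–retest arm's and the pooled t is
conservative when the larger group has the larger variance. The power
against regulation is carried by the correlation comparison, which rises
from ~0.05 at gamma = 0 to ~0.6 at gamma = 0.9 with these arm sizes. The
default 2000 replicates per gamma give Monte-Carlo standard errors below
0.011 on any rate and run in about a second.

## k3 → Ki sensitivity

The plasma-input influx constant Ki = K1·k3/(k2+k3) is a rectangular
hyperbola in k3, so a fractional change f in k3 maps to
`(1+f)(k2+k3)/(k2+(1+f)k3) − 1`, which for f > 0 lies strictly inside
(0, f) whenever k2 > 0, reaching 0 at k2 = 0 (saturation) and f as
k2/k3 → ∞ (linear regime). A fractional Ki change *larger* than the k3
change is therefore impossible under this formula. The empirical mode
re-estimates the change through the full simulate-and-fit pipeline on the
default grid (K1 = 0.04; k2 ∈ {0.04, 0.08, 0.16}; k3 ∈ {0.01, 0.02,
0.04} — the package's own grid, fully configurable): estimator distortion
reaches ≈ −5 percentage points at the slow-washout/low-trapping corner and
can slightly *exceed* the analytic value elsewhere, quantifying how the
finite-window graphical method bends the hyperbola.

## Degenerate inputs and error policy

Every operation validates its domain and raises a typed exception
(schedule gaps, non-positive baselines, zero-variance vectors,
rank-deficient designs, <3 usable Patlak frames, out-of-scan times); the
CLI maps any of them to a one-line `error:` message and exit code 2. The
battery downgrades *statistically* degenerate sub-results (e.g.
correlations of zero-variance percent changes on a noise-free null cohort)
to flagged entries instead of failing the whole report. All reports are
plain dicts that round-trip losslessly through JSON and embed the exact
configuration, seed and a config hash.

## Problem sizes used in tests

Monte-Carlo oracles use 10⁵–10⁶ subjects (vectorized, seconds); ICC
calibration uses 10⁴ subjects; noise-robustness uses 200 seeded replicate
curve pairs; battery calibration uses 2000 replicates per gamma; CI
coverage uses 200 seeded cohorts. These sizes put every Monte-Carlo
tolerance at least ~3 standard errors wide.

## Known limitations

* No image-space effects (attenuation, scatter, motion, partial volume,
  reconstruction), no radioactive decay, no arterial-sampling mode.
* The regulation model is linear-in-baseline with a single set point; real
  autoreceptor pharmacology is dose- and receptor-state-dependent.
* The reference-Patlak estimate carries the usual reference-tissue biases
  (non-zero reference trapping would bias Ki_cer; none is simulated).
* Steiger's dependent-correlation test is provided for completeness but
  the two-study design is independent; the package defaults to the
  independent-samples comparison.
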