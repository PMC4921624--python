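# Methods

This note documents the models implemented in `mapthresh`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Study design being emulated

The package reproduces a nested case–control analysis of CVD
hospitalisation in a type 2 diabetes register.  A *case* is a subject whose
first CVD admission falls inside a two-year window; the admission date is
the *index date*.  For each case, up to five controls are sampled by
**risk-set sampling**: uniformly at random, without replacement, from
subjects of the same sex and practice, within an age caliper, who are still
event-free at the index date.  Under risk-set sampling a subject may serve
as a control for several cases and may later become a case itself; this is
what makes the conditional-logistic odds ratio an estimate of the incidence
rate ratio rather than of a cumulative odds.

Design choices left open by the emulated design, and the defaults chosen:

* **Age caliper** — matching "by age" is implemented with a caliper
  (default ±2 years, configurable).  Exact-age matching starves risk sets
  at simulation scale.
* **Under-filled sets** — kept if at least one control is found (the
  conditional likelihood handles variable set sizes); the achieved
  case:control ratio is reported.  A fully matched design would achieve
  5.0; the default pipeline achieves ≈4.99, and partially filled sets are
  counted in the match-quality report.
* **Sampling scheme** — without replacement within a set, independent
  across sets (standard risk-set sampling).

## Event model of the synthetic cohort

Covariate marginals follow the control arm of the emulated study's
descriptive table: SBP 134.0 ± 11.1 and DBP 72.0 ± 10.0 mmHg (bivariate
normal, correlation 0.6, so MAP and pulse pressure have a realistic joint
distribution), BMI 29.0 ± 5.8 kg/m², HbA1c 7.4 ± 1.3 %, total cholesterol
4.2 ± 1.0, triglycerides 1.7 ± 0.9, HDL 1.2 ± 0.4, LDL 2.4 ± 0.8 mmol/L,
eGFR 56.6 ± 17.9 mL/min/1.73 m², smoking 65.8 %, lipid-lowering treatment
72.2 %, aspirin 53.7 %, CHD history 35.6 %, cerebrovascular history 14.4 %.
Quantities the table does not give are set to values typical of a UK type 2
diabetes register: age 70 ± 10 years, 55 % male, diabetes duration 7 ± 5
years, 18 practices.  Continuous draws are truncated to physiologic
supports; SBP/DBP pairs are redrawn in the (negligible-probability) event
SBP ≤ DBP.

Event times are exponential with a constant per-subject rate

```
rate_i = baseline_rate · exp( f(MAP_i, g_i) + Σ_c γ_c (x_ic − x̄_c) )
```

censored at 730 days of follow-up.  The case–control design carries no
hazard-shape information, so the simplest hazard that induces risk sets
suffices.  The MAP effect `f` is, by default, a **hinge** (piecewise linear
in log-rate) with nadir `theta_true` and HbA1c-group-specific slopes —
the hinge makes θ a well-defined estimand for threshold-recovery tests.
Defaults encode the qualitative pattern of the emulated study: below the
nadir the low-HbA1c group is steeper (0.05 vs 0.02 per mmHg); above it the
high-HbA1c group dominates (0.05 vs 0.005 per mmHg); `theta_true` = 97
mmHg; HbA1c cut at 7 % (53 mmol/mol); `baseline_rate` = 4 × 10⁻⁵ events
per person-day, which yields roughly 600–850 cases per 20 000 subjects over
two years — the scale of the emulated study (588 cases).  Smooth-quadratic
and purely linear effect shapes are available for robustness and
calibration studies.  Covariate effects default to a small set (CHD history
0.7, BMI 0.03, triglycerides 0.2 on the log-rate scale) so that the
baseline table shows realistic case–control contrasts; effects are centred
so `baseline_rate` keeps its meaning at the nadir.

**What the generator does not emulate**: missing data (GP records are
complete here), calendar time and practice-level clustering beyond a
categorical ID, antihypertensive-medication dynamics, and measurement error
in blood pressure.  Passing tests therefore demonstrate the estimators'
statistical properties under a clean data-generating process, not
robustness to those real-data complications.

### Direct matched-set simulation

Repeated-simulation studies (calibration, power, recovery, coverage) use
`simulate_matched_sets`, which draws the members of each matched set and
assigns the case by the conditional-logistic probabilities
`exp(lp_j)/Σ exp(lp_k)` implied by the true log-rate.  This *is* the
conditional likelihood's data-generating process — it is distributionally
equivalent to simulating exponential event times and risk-set sampling
controls, at a small fraction of the cost — and the full cohort → matching
path is exercised separately by its own tests and by the pipeline.

## Conditional logistic core

The conditional log-likelihood `Σ_s [x_case'β − log Σ_j exp(x_j'β)]` is
maximised by Newton–Raphson with analytic score and observed information,
step-halving, and a BFGS fallback if the information matrix is not usable.
Per-set reductions use `np.*.reduceat` over strata-sorted rows, with a
per-set max subtracted before exponentiation.  Convergence is
`max |score| < 1e-8`; the covariance is the inverse observed information at
the optimum.

* **Separation** — a monotone likelihood is detected when any
  `|β_j| × (within-set SD of column j)` exceeds 10 (an odds spread of
  e¹⁰ within a set); the fit is flagged not-converged with guidance rather
  than raised.
* **Collinearity** — a singular information matrix raises an error naming
  the offending columns (from the eigenvectors of its null space).
* Columns constant within every stratum carry no information under
  conditioning and are dropped with a warning; a design with no informative
  columns (all-concordant sets) raises a zero-information error.
* **VIF** — computed after within-stratum centring (the relevant scale for
  a conditional model), `VIF_j = 1/(1 − R²_j)`; perfectly collinear columns
  report infinity by name.
* **C-statistics** — the default "two-level" variant refits a logistic
  model with a random intercept per matched set, integrating the intercept
  by 15-node Gauss–Hermite quadrature, and computes the Mann–Whitney AUC of
  the *marginal* predicted probabilities over all case–control pairs (ties
  count ½).  The within-set variant scores concordance of the conditional
  linear predictor over within-stratum pairs only.  Quadrature failure
  falls back to the within-set variant with a logged warning.  The
  two-level reading of a "matched-set-fixed multilevel model" was chosen as
  the standard frequentist interpretation; both variants are reported.

## Spline dose–response

Three families model MAP inside the linear predictor:

* *linear* — MAP itself;
* *natural cubic* — truncated-cubic divided-difference basis on 3 interior
  knots plus boundary knots, C² everywhere and exactly linear outside the
  boundaries; `k_interior + 1` columns (the intercept is absorbed by
  stratification);
* *quadratic* — C¹ degree-2 truncated-power basis on the same interior
  knots.

"3 equally spaced knots determined from the levels of MAP" is read as the
1/4, 2/4, 3/4 points of [min(MAP), max(MAP)] with boundary knots at the
extremes; percentile-based knots are the sensitivity alternative
(`knot_rule="percentile"`), and `knot_sensitivity` tabulates AIC and curve
nadir across arbitrary knot sets, recording invalid sets as error rows.
Family choice is minimum AIC (ties toward fewer parameters; non-converged
families excluded with a warning).  Linearity is the LRT of spline vs
linear (the Wald joint test on the nonlinear coefficients is available).

The fitted curve reports `exp[(B(g) − B(ref))'β̂]` with delta-method
pointwise bands.  The **reference** defaults to the estimated nadir of the
fitted curve, so the curve reads as risk relative to the optimum
(configurable to any MAP value); rag counts use 1-mmHg bins.  Grid points
beyond the boundary knots are flagged as extrapolation.

## Threshold detection

Candidates run from the empirical P5 to P95 of MAP (linear-interpolation
percentile convention) in 1-mmHg steps.  At each candidate t the scan model
gains the hinge column (MAP − t)₊ and records AIC, the hinge coefficient,
and its Wald p.  The selected threshold is the candidate with `break_p <
0.05` achieving minimum AIC; ties break toward the candidate nearest the
scan median; an empty significant set returns an explicit no-threshold
status.

**Scan model.**  Two modes exist.  `segmented` (default) puts the hinge on
a linear MAP term, so the hinge coefficient is exactly the slope change at
t.  `spline_hinge` adds the hinge to the full natural cubic spline.  The
default is `segmented` because a cubic spline can absorb a kink smoothly:
in simulation at study scale (500 sets, hinge truth, slopes ±0.05/mmHg) the
spline+hinge break test is significant in fewer than half of replicates and
its AIC-minimising candidate is biased several mmHg low, whereas the
segmented scan detects the break in essentially every replicate and centres
on the true kink.  The spline remains the model for the dose–response curve
itself; the segmented model is used only to localise the break.

The CI is a **percentile bootstrap** (2.5/97.5, no BCa): matched sets are
the resampling unit (preserving the matched design), each replicate redraws
`n_sets` sets with replacement, rebuilds its candidate grid, and reruns
scan-and-select.  Replicates returning no threshold are counted separately;
more than 50 % of them flags the CI unreliable.  A percentile interval can
in principle fail to bracket the point estimate; this is logged, not
hidden.  The scan's multiplicity (many candidates at per-candidate α =
0.05) is deliberately uncorrected, mirroring the emulated analysis; the
null-scan simulation in the test suite quantifies the resulting
anticonservatism (a minority of linear-truth replicates still report a
threshold).

## Interaction and sensitivity analyses

The interaction model augments the adjustment set with (θ − MAP)₊,
(MAP − θ)₊, the high-HbA1c indicator (auto-dropped with a warning when
constant within every set), and the two segment × indicator products.
Group slopes are linear combinations of coefficients with exact SEs from
the coefficient covariance; per-segment interaction p-values are Wald tests
on the product terms.  HbA1c dichotomises at the usual ADA target — 7 %
goes to the *high* group; mmol/mol inputs compare against the rounded cut
(53) since the dual-unit target is quoted that way clinically.

Range restriction drops subjects outside [lo, hi] and any set whose case
(or all controls) is lost; early-admission exclusion removes whole sets
whose case occurred within the first 90 days.  Both re-report set counts so
every removed record is accounted for.

### Unmeasured-confounder bias array

For a binary confounder with prevalence `p0` among the unexposed,
`p1 = min(f·p0, 1)` among the exposed (exposure = MAP below the threshold;
default prevalence ratio f = 1.5) and confounder–outcome odds ratio γ, the
classical external-adjustment bias factor is

```
B(p0, γ) = (1 + p1(γ − 1)) / (1 + p0(γ − 1))
```

with `B(·, 1) = 1`, `B` increasing in γ, and `sup_γ B = p1/p0 = f`.  The
observed IRR for the array defaults to the segmented-model contrast 10 mmHg
below θ versus θ.  The *required factor* reported per `p0` is the effect
magnitude solving `B = IRR` — the confounder strength needed to fully
explain the association if no true effect existed.  Because relabelling the
confounder to its complement swaps a harmful factor γ for a protective
factor 1/γ, the magnitude is reported without a sign convention; when the
observed IRR meets or exceeds the prevalence-ratio bound f, no finite
effect suffices and the cell reports infinity.  Whether the emulated
analysis used this exact formula or a rule-out variant is not stated in its
description; the report labels the method used.

## Adjustment sets

The default adjustment set follows the dose–response figure captions of the
emulated study (CVD/cerebrovascular history, diabetes duration, BMI,
triglycerides, total/LDL/HDL cholesterol, eGFR, smoking, lipid-lowering and
aspirin treatment, pulse pressure); the narrower list from its methods text
(without eGFR, smoking, pulse pressure) is available as
`adjustment="methods"`.

## Numerical and reproducibility choices

* All percentiles use numpy's linear-interpolation convention.
* AIC is `−2ℓ + 2k`; ties in model selection break toward fewer parameters.
* AUC ties count 0.5 (Mann–Whitney convention).
* Every random step flows from one integer seed: the cohort, matching,
  and bootstrap share a `numpy` Generator chain, a run is reproducible from
  config + seed alone, and each written report embeds the config hash.
* CSV artefacts are comma-separated UTF-8 with a mandatory header; missing
  values are empty fields; a `# seed=...` comment records the seed.

## Problem sizes used by the checks

The test suite runs its simulation studies at "desk scale", chosen to make
the statistical assertions sharp while keeping the suite quick: threshold
recovery and bootstrap coverage at 500 sets × (1 case : 5 controls) over 50
replicates with 200 bootstrap samples; LRT calibration at 500 simulations
of 300 sets; interaction recovery at 100 replicates of 400 sets; generator
law checks at 50 000 subjects.  The acceptance script runs the full
pipeline once at study scale (20 000 subjects, ≈830 matched sets, 1000
bootstrap samples).  The bootstrap default in the library remains 1000.

## Known limitations

* The threshold estimator is grid-valued (1-mmHg default); sub-mmHg
  precision requires a finer scan step.
* The percentile bootstrap CI for a scan-selected breakpoint has no
  higher-order coverage guarantee; coverage at the default study conditions
  is verified empirically in the acceptance suite.
* The two-level C-statistic's quadrature fit uses derivative-free
  optimisation and can be slow for large adjustment sets.
* Under linear truth the uncorrected multi-candidate scan reports a
  spurious threshold in a minority of datasets (anticonservative by
  design, to mirror the emulated analysis).
* No robust/sandwich variances, time-varying covariates, weighting,
  two-breakpoint models, or penalised splines.
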