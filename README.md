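# mapthresh

Dose–response and threshold analysis of **mean arterial pressure (MAP)**
against cardiovascular (CVD) hospitalisation in matched case–control data
from a type 2 diabetes population.

Routine primary-care records suggest that in type 2 diabetes the risk of CVD
hospitalisation is **U-shaped in MAP** — elevated both below and above an
optimum near the high-90s mmHg — and that the low-MAP arm of the U is
steepest in patients with *well-controlled* HbA1c (< 7% / 53 mmol/mol),
while above the optimum risk rises mainly in the high-HbA1c group.  Source
records of that kind are not public, so `mapthresh` provides the full
analysis as a tested, reusable pipeline together with a synthetic cohort
generator that emulates the study design.  It is aimed at epidemiologists
and biostatisticians who want to run, check, or extend this class of nested
case–control dose–response analysis.

## What it computes

With MAP = [(2 × DBP) + SBP] / 3 and one case matched to up to five
controls by risk-set sampling (age, sex, practice), the conditional
likelihood for set *s* is

```
L_s(β) = exp(x_case'β) / Σ_{j∈s} exp(x_j'β)
```

and the fitted odds ratios estimate incidence rate ratios (IRR).  On top of
this core the package provides:

* **Spline dose–response** — linear, natural cubic (3 interior knots,
  linear beyond the boundary knots) and quadratic-spline bases for MAP,
  ranked by AIC; nonlinearity tested by the likelihood-ratio test of spline
  vs linear; the adjusted IRR curve with delta-method confidence bands and
  rag-plot counts.
* **Threshold detection** — a P5–P95 scan adding a hinge term (MAP − t)₊ to
  the scan model; the selected threshold is the significant break with
  minimum AIC; its CI comes from a percentile bootstrap that resamples
  matched sets and reruns the whole scan.
* **HbA1c interaction** — segmented slopes (θ − MAP)₊ and (MAP − θ)₊
  interacted with the HbA1c ≥ 7% indicator, with Wald tests per segment.
* **Sensitivity analyses** — MAP-range restriction (60–120 and 80–120
  mmHg), exclusion of admissions in the first three months, and an
  external-adjustment bias array for an unmeasured binary confounder.
* **Diagnostics** — variance inflation factors and C-statistics (two-level
  random-intercept logistic model fitted by Gauss–Hermite quadrature, plus
  within-set concordance).

## Worked example

```python
import mapthresh as mt

cfg = mt.AnalysisConfig(seed=1, n_subjects=20_000, n_boot=200,
                        two_level_cstat=False)
res = mt.run_pipeline(cfg, out_dir="demo_run")
est = res["threshold"]
print(f"sets: {res['n_sets']}  ratio: {res['match_report']['achieved_ratio']:.2f}")
print(f"selected family: {res['selected_family']}  linearity p: {res['linearity_p']:.2e}")
print(f"threshold: {est.threshold:.1f} mmHg  (95% CI {est.ci_low:.1f}-{est.ci_high:.1f})")
```

prints (seed 1):

```
sets: 832  ratio: 4.99
selected family: natural_cubic  linearity p: 8.94e-08
threshold: 93.6 mmHg  (95% CI 92.5-99.7)
```

Here the generator's true nadir is 97 mmHg: the matched design keeps the
full 1:5 control ratio, the AIC ranking picks the natural cubic spline, the
linearity test rejects decisively, and the scan-plus-bootstrap localises
the threshold with the true value inside the CI.  `demo_run/` then contains
the matched dataset, baseline table, AIC table, dose–response curve with
rag counts, threshold scan, bootstrap distribution and a compiled
`report.json`.

The same pipeline is scriptable from the shell:

```bash
mapthresh simulate --seed 1 --out cohort.csv
mapthresh match --cohort cohort.csv --out matched.csv
mapthresh fit --data matched.csv --out fit.json
mapthresh threshold --data matched.csv --n-boot 1000 --seed 1 --out threshold.json
```

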