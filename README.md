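# lcskit

A toolkit for **bivariate dual latent change score modeling** of four-wave
panel data, built around the question of how family functioning (FF) and
adolescent externalizing problems (EP) shape each other's change over time.
It is written for researchers in developmental psychopathology and
longitudinal methodology who want a fully scriptable, dependency-light
replication pipeline: a compact SEM engine, model builders, a measurement
invariance ladder, a calibrated synthetic-data module, and an end-to-end
study pipeline with a CLI.

## The model

Each construct is represented by latent true scores `x_1..x_T` behind the
observed wave composites, with latent change scores
`Δx_t = x_t − x_{t−1}`.  In the dual change score form each change is driven
by a constant slope factor, proportional feedback from the prior level, and
(from the second change onward) the prior change:

```
Δx_t = s_x + β_x·x_{t−1} + γ_xy·y_{t−1} + ξ_xy·Δy_{t−1} + φ_x·Δx_{t−1}
Δy_t = s_y + β_y·y_{t−1} + γ_yx·x_{t−1} + ξ_yx·Δx_{t−1} + φ_y·Δy_{t−1}
```

* `β` — proportional change (self-feedback of the prior level),
* `φ` — change autoregression,
* `γ` — level-to-change coupling across constructs,
* `ξ` — change-to-change coupling across constructs,
* `σ²_ex, σ²_ey` — measurement error variances.

The intercept factors `i_x, i_y` are the wave-1 true scores; all loadings
and accumulation paths are fixed at 1; every dynamic coefficient carries a
single label across waves (equality over time).  Estimation is normal-theory
ML on summary moments or full-information ML (FIML) on raw data with
missing values; fit is summarized by χ², CFI, TLI, RMSEA (with a 90%
noncentrality interval) and SRMR.

## Worked example

Simulate a study-sized cohort (n = 468, four waves) from the package's
fixed generative condition and refit the model:

```python
from lcskit.study_pipeline import fit_lcsm
from lcskit.synthetic_data import recovery_parameters, simulate_lcs

params = recovery_parameters()
data = simulate_lcs(params, 468, seed=7)
fit, caveats = fit_lcsm(data=data)
print(fit.chi_square, fit.df, fit.cfi)
for lbl in ("gamma_xy", "gamma_yx", "xi_xy", "xi_yx"):
    e = fit.estimate(lbl)
    print(lbl, e.value, e.se, e.p)
```

Output from this exact run:

```
converged: True  chi2(20) = 32.43  chi2/df = 1.62
CFI = 0.996  TLI = 0.995  RMSEA = 0.036 [0.008, 0.059]  SRMR = 0.018
  gamma_xy  =   0.507  (SE 0.085, p = 0.000)   true 0.45
  gamma_yx  =   0.209  (SE 0.090, p = 0.020)   true 0.25
  xi_xy     =  -0.474  (SE 0.149, p = 0.001)   true -0.37
  xi_yx     =  -0.367  (SE 0.165, p = 0.026)   true -0.46
  mu_xs     =  -5.546  (SE 1.789, p = 0.002)   true -3.825
  mu_ys     =   5.594  (SE 2.418, p = 0.021)   true 3.625
```

The couplings carry the study's sign pattern — levels of externalizing
problems predict subsequent family-functioning change positively (γ_xy),
while changes in each construct predict the other's subsequent change
negatively (ξ_xy, ξ_yx) — and every estimate sits within two standard
errors of its generating value.  Note the large slope-mean estimates with
large standard errors: the mean structure of this model family is
ill-conditioned (the wave means barely move), a point documented in
`docs/methods.md`.

The same stages are available from the shell:

```bash
lcskit simulate --mode moments --n 468 --exact --seed 1 --out data.csv
lcskit descriptives --data data.csv --columns FF_T1,FF_T2,EP_T1,EP_T2
lcskit fit-lcsm --data data.csv
lcskit run-study --config study.yaml --out out/
```

## Layout

| module | contents |
| --- | --- |
| `lcskit.sem_core` | model specification/compilation, implied moments, ML and FIML fitting, fit indices, standardization, nested comparison |
| `lcskit.lcs_models` | univariate/bivariate dual change score builders, trajectory recursion, covariate attachment |
| `lcskit.invariance` | configural → metric → scalar longitudinal CFA ladder with the ΔCFI ≤ 0.01 rule |
| `lcskit.synthetic_data` | published-moments fixture, moment-calibrated and generative samplers, 3-point item generator, missingness/attrition |
| `lcskit.study_pipeline` | descriptives, composition, attrition, reliability, invariance, LCSM fit, JSON reports |
| `lcskit.io`, `lcskit.cli` | moments/wide CSV formats and the `lcskit` command |
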