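# morbcompress

Tools for studying **multimorbidity compression** — the hypothesis that the
onset of chronic-disease burden is being pushed to later ages faster than
life expectancy grows — on cross-sectional health-surveillance data shaped
like the Italian PASSI system (adults 18–69, five self-reported
non-communicable diseases, socio-economic covariates, 19 regions, survey
years 2008–2019). It is written for biostatisticians and epidemiologists who
want a continuous, measurement-error-aware multimorbidity index and a
boundary-aware regression for it, plus a synthetic-data generator so the
whole chain is testable without access to restricted microdata.

## The model

**Multimorbidity index.** The five binary disease indicators
`X_ij ∈ {0,1}` are treated as reflective measurements of a latent trait
`z_j ~ N(0,1)` via a two-parameter logistic item model,

```
logit P(X_ij = 1 | z_j) = β0_i + β1_i z_j ,
```

estimated by an EM algorithm with fixed-grid quadrature (Bock–Aitkin).
The likelihood is weighted per respondent by

```
w_j = (D_j + 1) N / (Σ_j D_j + N) ,   D_j = 1 − Π_i (1 − W_ij) ,
```

where `D_j` is a cumulative GBD-style disability weight: each reported
condition contributes a severity weight `W_ij`, picked from a per-disease
candidate set by the respondent's perceived health (ratings 1–3 → minimum,
4 → mean, 5 → maximum). Respondents are scored by the posterior mean (EAP)
of `z`, and scores are rescaled to `y ∈ [0,1]`.

**Compression regression.** The rescaled index has structural point masses
at 0 (no disease) and 1 (worst observed pattern), so `y` is modelled with a
zero/one-inflated **ordered beta regression**: a logistic zero part, an
ordered-logit cutpoint separating the one-mass from the interior, and a
mean–precision Beta density inside `(0,1)`, with a regional random
intercept `u_k ~ N(0, σ²_u)` on the conditional predictor integrated out by
a Laplace approximation. Fixed effects: sex, age, education, economic
status, survey year and sex×age. A negative conditional **year**
coefficient is the compression signal. Population-level predictions combine
the parts as `ŷ = (1 − γ̂)·μ̂` with random effects set to zero, and
regional BLUPs summarise spatial heterogeneity. Refitting the regression
inside risk classes 0–4 (count of smoking, alcohol, poor diet, physical
inactivity) checks whether compression persists at fixed behaviour.

## Worked example

```python
import dataclasses
import morbcompress as mc

eff = dataclasses.replace(mc.LatentEffects(), per_year=-0.06)  # clear secular decline
pop = dataclasses.replace(mc.PopulationConfig(), n_respondents=20_000, seed=7,
                          latent_effects=eff)
report = mc.run_pipeline(mc.PipelineConfig(population=pop))
print(report.item_params.round(3).to_string(index=False))
print(report.year_effects.round(4).to_string(index=False))
```

prints

```
    disease  neg_beta0  beta1  se_beta0  se_beta1
   diabetes      3.515  1.401     0.083     0.079
     kidney      5.802  2.060     0.229     0.146
respiratory      2.859  1.054     0.053     0.060
      heart      3.707  1.517     0.096     0.087
      tumor      3.171  0.944     0.056     0.061

        stratum  estimate     se       t
full population   -0.0153 0.0025 -6.0163
   risk class 0   -0.0171 0.0057 -2.9907
   risk class 1   -0.0140 0.0040 -3.5022
   risk class 2   -0.0167 0.0046 -3.6428
   risk class 3   -0.0100 0.0088 -1.1390
   risk class 4    0.0001 0.0359  0.0021
```

The first table is the fitted measurement model (reported as −β0 and β1 per
disease, matching the generating values: rare kidney failure is the most
discriminating condition, tumours the least). The second table shows the
conditional year effect: clearly negative overall and in the well-populated
risk classes — the compression signature — while the small classes 3 and 4
(a few hundred respondents here) are too noisy to resolve it. Prediction
grids, the regional BLUP table and per-cell behaviour frequencies are also
on the report; `report.report_hash()` fingerprints the whole output for
reproducibility.

The same stages are scriptable from a shell:

```
morbcompress simulate --out pop.csv --seed 7 --n 20000
morbcompress weights --pop pop.csv --out weights.csv
morbcompress fit-ltm --pop pop.csv --weights weights.csv \
    --out-params params.csv --out-scores scores.csv
morbcompress fit-ordbeta --scores scores.csv --pop pop.csv --out fit.csv
morbcompress pipeline --out reportdir/ --seed 7 --n 20000
```

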