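# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `morbcompress`, in the spirit of the methods
documentation of estimation-heavy scientific packages.

## 1. Measurement model: weighted two-parameter latent trait

Five self-reported chronic conditions (diabetes, kidney failure,
respiratory disease, heart disease, tumor) are reflective indicators of a
scalar multimorbidity trait `z ~ N(0,1)`:

    logit P(X_i = 1 | z) = β0_i + β1_i z .

`expit(β0_i)` is the prevalence of condition *i* at average multimorbidity;
`β1_i` (the discrimination) measures how sharply the condition separates
low from high burden. The latent scale is identified by fixing the prior at
N(0,1) and, because of the 2PL sign invariance, by flipping all slopes and
scores if the mean slope comes out negative.

**Disability weighting.** Estimation maximises a weighted marginal
likelihood with per-respondent weights

    w_j = (D_j + 1) N / (Σ D_j + N),   D_j = 1 − Π_i (1 − W_ij),

so the weights average to one and up-weight respondents carrying a heavier
burden. `W_ij` comes from a per-disease catalogue of candidate severity
weights in (0,1); the respondent's perceived health selects the candidate
(1–3 → minimum, 4 → mean, 5 → maximum). Weights equal to 0 or 1 are
rejected at catalogue load: a unit weight would force `D = 1` and break the
weight formula's interpretation. The packaged default catalogue is a fixed,
versioned *synthetic* stand-in with plausible severity orderings (it is not
the GBD health-state table; matching disease names to GBD health states is
out of scope). Weights are recomputed per dataset because every `w_j`
depends on the sample sum of `D`.

**Estimation.** EM in the Bock–Aitkin tradition. The marginal integral is
replaced by a fixed grid; the default is 61 equally spaced nodes on
[−6, 6] carrying renormalised standard-normal masses, with a Gauss–Hermite
grid available as an option. Response patterns are collapsed (≤ 2⁵ distinct
patterns) with their summed weights, which makes the EM cost independent of
sample size. The E-step distributes each pattern over the nodes by its
posterior; the M-step solves one weighted logistic regression per item by
Newton iterations (inner tolerance 1e-10). Starting values: `β0` at the
logit of observed prevalence, `β1 = 1`. Convergence: maximum absolute
parameter change < 1e-4 (configurable), cap 500 iterations; exceeding the
cap flags the fit rather than failing. The weighted log-likelihood is
checked to be non-decreasing across iterations in the test suite, and
doubling the node count moves the converged log-likelihood by < 1e-3.

Standard errors use the empirical cross-product of per-pattern score
contributions (outer product of pattern-level gradients, weighted by total
pattern weight) — a pseudo-likelihood information estimate appropriate
under the externally supplied weights.

**Scoring.** Respondents are scored by the posterior mean (EAP) on the
grid: finite for every pattern, equal patterns get equal scores, and
turning any 0 into a 1 can never lower the score (verified by enumeration
of all 32 patterns). Scores are rescaled affinely to [0,1] using the pooled
sample extremes; consequently the rescaled index is exactly 0 precisely for
the all-zero pattern and exactly 1 for the worst observed pattern. These
point masses are treated as structural in the regression stage. Per-year
extremes are not used; the pooled convention keeps one common scale across
survey years.

The analytic degrees of freedom of the limited-information (M2-type) fit
statistic are provided for reference: univariate plus bivariate margins
minus two parameters per item, which equals 5 for five items. The statistic
itself (and RMSEA/SRMSR/TLI/CFI, item-level fit, semi-parametric latent
densities) is out of scope.

## 2. Outcome model: zero/one-inflated ordered beta regression

The rescaled index `y ∈ [0,1]` mixes two point masses with a continuous
interior. The default **hurdle** parameterisation is

    P(y = 0)            = expit(X β_zero)                     (zero part, no random effect)
    P(y = 1 | y > 0)    = expit(X β + u_k − k2)
    y | 0 < y < 1       ~ Beta(mean = expit(X β + u_k), precision ψ),
    with the interior probability (1 − P(y=0)) (1 − expit(X β + u_k − k2)),

which guarantees the three components sum to one and matches the
population-level composition formula `ŷ = (1 − γ̂) μ̂`. The single-predictor
**canonical** ordered beta model with two cutpoints `k1 < k2` on one linear
predictor is kept as an option (`variant="canonical"`); with constant
covariates the hurdle family reproduces it exactly after matching the zero
line and cutpoint, which is kept as a regression test. The hurdle default
was chosen because a specification with a separate zero-line coefficient
vector and no random effect in the zero line does not define a coherent
single-predictor ordered model; making the zero part an explicit hurdle is
the internally consistent reading, and it mirrors the common reporting
convention of a separate "zero-inflation model" coefficient block.

**Covariates and coding.** Intercept, sex, age, economic status, education,
survey year, sex×age. Internally (and in reports) age is centered at 43.5
years and year enters as the offset from the first observed survey year:
the intercept is then the predictor of a 43.5-year-old woman with low
education and economic difficulties in the first year, and "Sex (Male)" is
the sex contrast at age 43.5. Slopes per year of age or calendar time are
unaffected by the coding; the centering decorrelates the main effects from
the interaction, which both conditions the optimiser and makes simulation
recovery of each coefficient individually meaningful. Likelihood invariance
to shifting the calendar origin is tested.

**Random effect and marginalisation.** `u_k ~ N(0, σ²_u)` enters the
conditional (`y > 0`) predictor of each of the K = 19 regions. The marginal
likelihood integrates each region's contribution over `u_k` by a Laplace
approximation: an inner Newton finds the per-region mode using analytic
first and second derivatives of the joint log-density (digamma/trigamma
terms for the Beta part), vectorised across regions and warm-started
between evaluations (inner tolerance 1e-10, so results are independent of
the warm start — row-permutation invariance holds to 1e-8 thanks to an
internal canonical row ordering). A 15-node adaptive Gauss–Hermite
quadrature is available as a cross-check; on a 3-region toy set it agrees
with the Laplace value within 5e-2, and the σ_u → 0 limit reproduces the
no-random-effect likelihood to 1e-4.

**Fitting.** Maximum likelihood with L-BFGS-B on the unconstrained
parameterisation (`k2` free in the hurdle; `k2 = k1 + exp(δ)` in the
canonical variant to enforce ordering; `log ψ`, `log σ_u`). Starting
values: cutpoints −1 and 1 (canonical) or `k2 = 1` (hurdle), `β` from a
least-squares fit to the logit of interior outcomes, the zero part from a
ridge-damped IRLS warm start (which also raises a separation warning when
warm-start coefficients explode), `ψ = 5`, `σ_u = 0.1`. Random-effect fits
are two-staged: the no-random-effect model is optimised first (one
likelihood pass per evaluation) and seeds the full fit. After L-BFGS-B, a
damped Newton polish using the central-difference Hessian removes the
residual gradient along badly scaled directions; the converged flag
requires the optimiser's own success and a scaled gradient norm
(max |g_i|·max(1,|θ_i|) / max(1,|nll|)) below 1e-5. Standard errors come
from the inverse central-difference Hessian (via
`statsmodels.tools.numdiff.approx_hess`); t statistics use the normal
reference.

**Degenerate boundary components.** Fitting requires interior observations.
By default the data must also exhibit both point masses
(`components="strict"`), otherwise the error advises the reduced model;
`components="auto"` drops the absent mass(es) — e.g. the one-mass when a
stratum contains nobody at the sample maximum — and is what the pipeline
uses for per-risk-class refits, where exact ones are typically confined to
a handful of respondents holding the worst pattern. Interior values are
used untransformed (no boundary squeezing): the zero/one masses here are
structural, not censoring artifacts. Likelihood weights `w_j` are *not*
applied in this stage by default (a `weights=` argument exists): the
disability weighting belongs to the measurement-model likelihood.

**Post-fit quantities.** Population-level predictions set `u = 0`:
`γ̂ = P(y=0)`, `μ̂ = q̂1 + (1 − q̂1)·m̂` with `q̂1` the conditional one-mass
and `m̂` the Beta mean, `ŷ = (1 − γ̂) μ̂`. BLUPs are the per-region inner
modes (empirical-Bayes predictions) with conditional standard deviations
`1/sqrt(−g″)`; under a null random effect they collapse toward zero, and
they are always at most as large as the unpenalised per-region offsets
(shrinkage), both verified in tests.

## 3. Synthetic populations

The generator emulates the surveillance structure the models are meant for:
n respondents over 19 regions and years 2008–2019, ages uniform on 18–69,
sex/education/economic shares at the published survey composition (53.18%
female, 60.17% high education, 52.77% economic difficulties). A latent
trait is drawn standard normal, shifted by configured covariate effects
(age, sex, education, economic status, calendar year, sex×age, plus
regional intercepts with sd 0.10), then **re-standardised so the marginal
is exactly mean-0, variance-1** — keeping the generator consistent with the
estimator's identification. Diseases are Bernoulli draws from the 2PL
curves at the published item parameters; perceived health follows a
proportional-odds model in the trait (cutpoints −1.0, 1.2, 2.8, 4.2, slope
1.0, giving roughly 30/43/19/6/2 percent for ratings 1–5 — the link between
perceived health and the trait has no published counterpart, so this is a
configurable stand-in); the four risk behaviours are Bernoulli with mild
regional and secular logit gradients around realistic adult prevalences
(smoking ≈ 30%, risky alcohol ≈ 17%, poor diet ≈ 50%, inactivity ≈ 35%).
Default latent effects encode the qualitative published gradient pattern
(burden rising with age, higher under economic difficulty and low
education, slowly declining in calendar time at −0.015 sd/year).

Ground-truth columns (`z_true`, regional effect) are written to a sidecar
file by `write_population`, never to the survey CSV, to prevent leakage
into estimation. Identical seeds give byte-identical tables.

What the generator does **not** emulate: the true survey's sampling design
and non-response, regional population sizes (regions are uniform),
item-level local dependence, or any mortality selection. Passing tests
therefore demonstrate internal consistency of the estimators under the
assumed data-generating process, not robustness to those real-data
features.

## 4. Pipeline and calibration experiments

`run_pipeline` chains: simulate/load → disability weights → weighted 2PL →
EAP scores → rescale → full-population hurdle fit with regional random
effect → per-risk-class refits without random effects (reusing the pooled
scores and the full fixed-effect design — one measurement model, many
regressions) → prediction grids, BLUPs, behaviour-frequency tables, and a
SHA-256 report hash over all numeric outputs for bit-identical re-runs.
Failures abort with the stage name after persisting earlier artifacts.

Problem sizes in the shipped experiments were chosen a priori so that every
asserted quantity has comfortable statistical margins at desk scale:

* measurement-model recovery: one simulation of n = 20,000 at the published
  item parameters (the rare kidney item dominates the sampling noise);
* EM-vs-direct-optimiser agreement: n = 200 with a shared quadrature grid;
* regression recovery: n = 10,000, 19 regions, ψ = 8, σ_u = 0.3;
* year-effect calibration: 20 seeded pipeline runs of n = 5,000 for the
  signed case and n = 2,500 for the null case. The signed-case population
  uses elevated disease prevalence (item intercepts +1.5, cutting the zero
  share to ≈ 50%), half-probability behaviours (so the extreme risk classes
  hold ≈ 6% of respondents each), and a −0.15 sd/year latent decline; a
  back-of-envelope power calculation puts the conditional-year t around
  −3 in the smallest stratum, i.e. ≈ 99% per-class sign power, which a
  19-out-of-20-seeds rule then tolerates. These are stress-test
  configurations for the estimator, not realistic epidemiological rates.

## 5. Known limitations

* The Laplace approximation is unchecked beyond the shipped quadrature
  cross-checks; with very small regions or extreme zero-inflation the
  marginal likelihood may be less accurate.
* The ML variance component `σ̂_u` carries the usual downward finite-K bias
  (no REML analogue is provided), and with 19 regions its sampling error is
  substantial.
* Standard errors of the measurement model ignore the sampling variability
  of the disability weights themselves (the catalogue is treated as fixed).
* EAP scores are shrunken toward zero; downstream regression coefficients
  are therefore attenuated relative to effects on the true latent scale.
  Sign and ordering conclusions are unaffected, absolute magnitudes are
  conservative.
* The rescaling to [0,1] is sample-dependent (pooled extremes), so
  coefficients are comparable across strata within one dataset but not
  across datasets with different worst-observed patterns.
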