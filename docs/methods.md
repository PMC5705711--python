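# Methods

## Model

The package implements the standard single-season (static) site-occupancy
model. Each of S sites has a latent state z_i ~ Bernoulli(ψ_i); visits to
an occupied site yield detections y_it ~ Bernoulli(p_it), visits to an
unoccupied site always yield y_it = 0 (no false positives). Integrating
the latent state gives the site likelihood

    L_i = ψ_i ∏_t p_it^{y_it}(1−p_it)^{1−y_it}      (some detection at i)
    L_i = ψ_i ∏_t (1−p_it) + (1−ψ_i)               (no detection at i)

with products over surveyed occasions only: a missing visit contributes
no factor (occasion-wise deletion), which is exact under the model and
handles ragged monthly designs with 4–6 nights per month. The model
assumes closure (z_i constant over the occasions being analysed),
independence between sites, and no misidentification. Dynamic
(multi-season) models with colonization/extinction are out of scope.

Both parameters live on logit links: logit ψ_i = x_i'β_ψ,
logit p_it = w_it'β_p. Continuous covariates are centred and scaled to
unit variance before fitting (the scalers are frozen in the fit object
and reused for prediction); categorical covariates are dummy-coded
against the alphabetically first level.

## Fitting

The negative log-likelihood is minimized by L-BFGS-B with an analytic
gradient, parameters boxed to |logit| ≤ 15, gradient tolerance 1e-8.
Occupancy likelihoods can be multimodal near the parameter boundary, so
fitting is multi-start (default 5 starts): the first start comes from
moment estimates (naive occupancy corrected by the cumulative detection
probability; raw detection rate at detected sites), the rest are seeded
N(0,1) perturbations. Standard errors come from the inverse observed
information, computed by central differences of the analytic gradient;
a fit is flagged `converged=False` when the optimizer fails its
tolerance, the information matrix is not positive definite, or the
optimum sits on the boundary. Confidence intervals for predicted ψ and
p are formed on the logit scale and back-transformed, so they always
lie inside (0,1).

Degenerate data are short-circuited rather than optimized: zero
detections anywhere pins ψ̂ to 0 (p inestimable, reported 0), and
detections on every visit at every site pin ψ̂ = p̂ = 1; both are
flagged as boundary fits. A dedicated constant-model kernel
(`fit_constant`) works from the sufficient statistics (per-site
detection and visit counts, grouped) and is what the simulation and
power modules call — it agrees with the general fitter to ~1e-5 and is
~50× faster, which is what makes 2000-iteration Monte-Carlo runs cheap.

## Model selection

Models are ranked by AIC = 2k − 2·log L̂ with Akaike weights
exp(−Δ_i/2)/Σ exp(−Δ_j/2); ties break by fewer parameters, then name.
Selection is two-stage stepwise: stage 1 keeps ψ constant and compares
the constant-p model with each single detection covariate; detection
structures within 2 AIC units of the stage-1 best are retained
("strong support" threshold). Stage 2 crosses each retained detection
structure with constant ψ and each single occupancy covariate.
Candidate covariates first pass a pairwise correlation screen: of any
numeric pair with |Pearson r| > 0.7 the later-listed one is dropped and
logged (0.7 is the conventional collinearity screen). Non-convergent
candidates are logged and excluded from the ranking, never silently
ranked.

## Design arithmetic and simulation

Minimum occasions to infer absence: the smallest integer K with
1−(1−p)^K ≥ p\*, computed as ⌈log(1−p\*)/log(1−p)⌉ with a 1e-12
tolerance before the ceiling so exact-integer ratios (e.g. p = 0.5,
p\* = 0.875 ⇒ K = 3 exactly) are not inflated by float error.

Estimator-precision simulation: for a scenario (ψ, p, S, K), each
iteration draws latent states, draws detections, and refits the
constant model; the summary reports mean, median, SD, bias, RMSE and
2.5/97.5 percentiles of ψ̂ and p̂ plus the boundary-fit rate.
Degenerate datasets are counted in `boundary_rate` and excluded from
the moment summaries — they are never re-drawn, because re-drawing
would bias the estimator distribution the module is meant to display.
Randomness uses one generator per (master seed, S, K) cell, so every
grid cell reproduces identically regardless of evaluation order.

## Power analysis

The asymptotic variance of the constant-model occupancy MLE is
var(ψ̂) = v/S with

    v = ψ[(1−ψ) + (1−p*)/(p* − K p (1−p)^{K−1})],   p* = 1−(1−p)^K,

the binomial-proportion floor ψ(1−ψ) plus an imperfect-detection
penalty that vanishes as p\* → 1. K = 1 is rejected (ψ and p are
non-separable from a single visit). Two-tailed Wald power for a change
ψ1 → ψ2 over two equally sized survey periods is

    G = Φ(Δ/SE − z_{α/2}) + Φ(−Δ/SE − z_{α/2}),
    Δ = ψ1 − ψ2,  SE² = (v1 + v2)/S,

which reduces exactly to α at Δ = 0. Required sites start from the
closed form S = ⌈(z_{α/2}+z_β)²(v1+v2)/Δ²⌉ and are then verified
against `wald_power` directly so the returned S is the smallest integer
achieving the target (the closed form ignores the far tail, which can
shift the answer by one site at tiny effects).

The empirical companion simulates both periods, refits each with the
constant-model kernel, and applies z = (ψ̂1−ψ̂2)/√(se1²+se2²),
rejecting when |z| > z_{α/2}. Standard errors on the probability scale
are taken from the closed-form variance factor evaluated at the fitted
values — consistent with the analytic calculation being verified — with
estimates clamped to [1e-6, 1−1e-6] first; an iteration with a
non-finite statistic counts as a non-rejection, and the degenerate
count is reported rather than hidden.

**Effect-size convention.** `effect_convention="proportional"`
(ψ2 = ψ1(1−R)) is the default and `"absolute"` (ψ2 = ψ1−D) is
available; the convention is mandatory in every report because a "30%
change" is ambiguous between them. The design-question defaults
(ψ1 = 0.49, p = 0.61, α = 0.1, K = 20) describe a pooled four-month
season whose cumulative detection probability is ≈ 1; power at that
operating point is insensitive to K for K ≥ 12.

## Synthetic data generator

The generator emulates a real monitoring design so the fitting,
selection, design and power stages can be tested end-to-end against
known truth: 48/48/47 sites in low/medium/high elevation bands
(1704–1815, 1838–1925, 1998–2060 m a.s.l., drawn uniformly within
bands), categorical zone occupancy 0.14/0.66/0.66, nightly detection
0.61/0.38 by observer experience with the two survey teams alternating
nights (configurable to random assignment), and 4 monthly surveys of
4–6 nights (drawn uniformly from that range, since the realized
schedule is a field decision). Plant-morphology covariates (size,
rosette volume, leaf and neighbour counts) are decoys drawn
independently of the latent state; time-after-dusk is uniform over
10–300 minutes with no true effect. An optional neighbour history
duplicates each site's latent state with fresh detection draws — the
minimal choice that exercises the pooling rule (entrywise OR with an
observed absence outranking a missing visit).

What the generator does **not** emulate: between-month movement or
turnover, abundance-driven detection heterogeneity, spatial
correlation, weather, or observer learning. Passing tests therefore
demonstrate correctness of the estimators and procedures under the
model's own assumptions, not robustness to their violation in field
data.

Two-period generation rescales zone occupancies by (1−R) and redraws
states and detections independently, holding sites, covariates and the
observer schedule fixed — matching a revisit design.

## Problem sizes and tolerances

Monte-Carlo checks in the test suite run at 2000 iterations for
estimator-distribution and empirical-power checks and 200 replicates
for selection-consistency/coverage checks — large enough that 3
binomial standard errors separate signal from seed luck, small enough
to keep the suite under a minute of simulation per check. Likelihood
values are checked against latent-state enumeration to 1e-10; the
constant-model MLE against a 0.001-step grid search. All stochastic
tests fix their seeds.

## Known limitations

- Single-season only; no colonization/extinction, misidentification or
  abundance-heterogeneity extensions.
- The Wald power calculation is asymptotic; at small S (≲ 50) with low
  p it can be optimistic, which is exactly what `empirical_power` is
  for.
- The stepwise procedure considers single-covariate structures per
  stage; interactions and multi-covariate detection models must be fit
  explicitly through `fit_occupancy`.
- `required_sites` assumes equal S in both periods; unequal designs
  are not exposed.
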