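# occudesign

Survey-design and power-analysis tools for species monitoring built on
single-season site-occupancy models with imperfect detection.

## The problem

Monitoring programmes for rare or cryptic species must answer three
questions before committing field effort: does the current design give
precise estimates of occupancy (ψ, the probability a site is occupied)
and detectability (p, the probability of detecting the species on one
visit to an occupied site)? Does it have enough statistical power to
detect a change in occupancy over time? And if not, is it better to add
visits or sites? `occudesign` answers all three for designs based on
the standard single-season occupancy model, whose site-level likelihood
is the zero-inflated binomial

```
L_i = ψ_i ∏_t p_it^{y_it} (1−p_it)^{1−y_it}        if site i had a detection,
L_i = ψ_i ∏_t (1−p_it) + (1−ψ_i)                   otherwise,
```

with products over surveyed occasions only and both parameters on logit
links with optional site- and survey-level covariates. On top of the
fitting machinery the package provides:

- **Minimum visits to infer absence**: the smallest K with
  1−(1−p)^K ≥ p\*, i.e. K = ⌈log(1−p\*)/log(1−p)⌉.
- **Estimator-precision simulation**: the sampling distribution (bias,
  RMSE, quantiles, boundary-fit rate) of the constant-model MLEs over a
  grid of candidate (S sites × K occasions) designs.
- **Wald power on the probability scale**: the power to detect a change
  ψ1 → ψ2 between two survey periods,
  G = Φ(Δ/SE − z_{α/2}) + Φ(−Δ/SE − z_{α/2}) with Δ = ψ1−ψ2 and
  SE² = (v1+v2)/S, where v = ψ[(1−ψ) + (1−p\*)/(p\* − Kp(1−p)^{K−1})]
  is the per-site asymptotic variance factor of ψ̂; plus the inverse
  problem (sites required for a target power) and a Monte-Carlo
  companion that verifies the normal approximation by simulation.
- **A synthetic study generator** that emulates a real monitoring
  design — 143 bromeliad "sites" in three altitudinal zones with
  zone-dependent occupancy (0.14/0.66/0.66), observer-dependent
  nightly detection (0.61 experienced / 0.38 inexperienced), and 4–6
  survey nights per month — with a truth ledger for end-to-end testing.

It is aimed at quantitative ecologists and monitoring practitioners
designing or auditing occupancy-based programmes.

## Worked example

```python
from occudesign import (StudyGeneratorConfig, generate_study, fit_occupancy,
                        stepwise_select, min_occasions, PowerSpec, wald_power,
                        empirical_power, required_sites)

study = generate_study(StudyGeneratorConfig(), seed=7)   # 143 sites, 18 occasions
fit = fit_occupancy(study.history, seed=0)
print(f"psi_hat={fit.psi_hat:.3f} p_hat={fit.p_hat:.3f}")
# psi_hat=0.552 p_hat=0.495

table, best = stepwise_select(
    study.history, study.site_covariates, study.survey_covariates,
    p_candidates=["observer_experience", "time_after_dusk"],
    psi_candidates=["elevation", "bromeliad_size"], seed=0)
print(best.spec.name)        # psi(elevation)p(observer_experience)

print([min_occasions(fit.p_hat, ps) for ps in (0.8, 0.9, 0.95)])
# [3, 4, 5]  visits needed to infer absence at rising confidence

spec = PowerSpec(psi1=0.49, effect=0.30, p=0.61, n_occasions=20,
                 n_sites=143, alpha=0.1)                 # proportional decline
print(f"{wald_power(spec):.3f}")                         # 0.817
res = empirical_power(spec, n_iter=2000, seed=1)
print(f"{res.empirical_power:.3f}")                      # 0.807 (MC SE 0.009)

print(required_sites(PowerSpec(psi1=0.49, effect=0.15, p=0.61,
                               n_occasions=20, alpha=0.1, target_power=0.8)))
# 565
```

Reading the output: the constant model recovers the generating mixture
(mean ψ ≈ 0.49, mean p ≈ 0.50); stepwise AIC selection identifies the
true covariate structure; three to five visits suffice to call a site
unoccupied; the 143-site design has ~82% power against a 30%
proportional decline, confirmed by Monte-Carlo, while detecting a 15%
decline at 80% power would need 565 sites.

Note the effect-size convention: `effect=0.30` means ψ2 = ψ1·(1−0.30)
(proportional). An absolute difference is available via
`effect_convention="absolute"`, and every report echoes the convention
in force — "a 30% change" is ambiguous without it.

The same workflow is available from the shell:

```sh
occudesign generate --seed 7 --outdir data/
occudesign select --history data/history.csv --site-covs data/site_covariates.csv \
    --survey-covs data/survey_covariates.csv \
    --p-candidates observer_experience,time_after_dusk \
    --psi-candidates elevation,bromeliad_size --seed 0 --out selection.csv
occudesign design-k --p 0.56 --p-star 0.8 --p-star 0.9 --p-star 0.95
occudesign sites --psi1 0.49 --effect 0.15 --p 0.61 --occasions 20 \
    --alpha 0.1 --power 0.8
occudesign run --config examples/demo.yaml --outdir report/   # full pipeline
```

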