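# trophdyn

Trait-based trophic analysis of moth and bird monitoring data: do
fluctuations in prey (moth) biomass propagate bottom-up to predator
(forest bird) biomass one year later?

The package is aimed at ecologists working with long-term monitoring
series — light-trap moth counts, breeding-bird point counts and
line-transect habitat strips, gridded breeding-season climate — who
want to estimate lagged prey effects on predator abundance at the
functional-group level. It provides the full chain as a tested,
reusable pipeline:

1. **Functional grouping and biomass** (`trophdyn.traits`) — breeding
   pairs x 2 x species body mass for birds; trap counts x regression-
   predicted specimen mass (wingspan + body plan) for moths; pooling
   into bird groups (migratory strategy x caterpillar reliance, 11
   populated combinations) and moth groups (overwintering stage:
   larva, adult/egg, pupa) after an "easy prey" filter.
2. **Covariates** (`trophdyn.covariates`) — per-trap ln-anomalies of
   moth-group biomass, inverse-distance interpolation to bird sites
   with leave-one-trap-out validation, climate anomalies, one-year
   lagging and standardization.
3. **The model** (`trophdyn.model`) — a joint dynamic species
   distribution model: Poisson-link delta-Gamma observations,

       Pr[B = 0] = 1 - r1,   B | B > 0 ~ Gamma(mean r2, CV sigma_m),
       r1 = 1 - exp(-a n),   r2 = a n w / r1,
       n = exp(p1),          w = exp(p2),

   where both linear predictors carry group intercepts (AR1 over years
   on the density predictor), standardized covariate effects,
   factor-analytic Matern spatial and spatio-temporal Gaussian fields,
   census-route overdispersion and census-type effects. Fixed effects
   maximize a Laplace-approximated marginal likelihood; random effects
   are predicted at the joint-likelihood mode.
4. **Inference** (`trophdyn.inference`) — delta-method standard
   errors, Bonferroni-adjusted Wald intervals (e.g. 99.8% for 2
   predictors x 11 groups, per-test alpha 0.002), empirical
   effect-size exceedance probabilities, and a time-lag sensitivity
   analysis by marginal AIC.
5. **Synthetic data** (`trophdyn.synth`) — a generative twin with
   known ground truth (sites, Matern fields, AR1 intercepts,
   delta-Gamma observations, specimens, climate), so every stage is
   testable without any data download.

A `trophdyn` command-line interface orchestrates fixture generation and
the full analysis (`synth`, `fit`, `effects`, `lag-sens`, `all`).

## Worked example

Simulate the standard recovery scenario (60 sites, 10 years, 3 groups,
a standardized prey-anomaly covariate with true effect 0.4 on the
density predictor) and fit the model:

```python
from trophdyn import fit_jdsdm, ModelConfig, effects_table, adjusted_ci_level
from trophdyn.synth import recovery_scenario

biomass, sites, design, truth = recovery_scenario(
    n_sites=60, n_years=10, n_groups=3, effect=0.4, seed=7)
config = ModelConfig(
    n_factors_spatial=1, n_factors_spatiotemporal=0,
    fields_on_predictor2=False, covariates_on_predictor2=False,
    year_effects_2="constant", seed=0)
fit = fit_jdsdm(biomass, sites, design, config)
eff = effects_table(fit, level=adjusted_ci_level(0.05, 2, 3), predictors=(1,))
```

which prints (converged, marginal NLL 4136.4; estimated AR1 rho 0.19,
innovation sd 0.26, Matern range 55 km):

```
bird_group covariate  estimate    se  ci_low  ci_high  significant
        G1        x1     0.433 0.071   0.245    0.622         True
        G2        x1     0.436 0.071   0.248    0.623         True
        G3        x1     0.373 0.060   0.215    0.532         True
```

All three group-level effect estimates bracket the true value 0.4, and
each multiplicity-adjusted interval (here 99.2% for 2 predictors x 3
groups) excludes zero: the bottom-up coupling is detected.

The same analysis from the shell, on generated fixture files:

```sh
trophdyn synth bottomup_strong --seed 1 --out fx
python -c "from trophdyn import PipelineConfig; \
           PipelineConfig(input_dir='fx', region='NB').to_yaml('cfg.yaml')"
trophdyn all --config cfg.yaml --seed 1 --out run
trophdyn lag-sens --config cfg.yaml --lags 0,1,2
```

Each run directory contains `effects.csv`, `fit.json`, the
interpolation validation, and a `manifest.json` with the seed and
config hash needed to reproduce it exactly.

## Layout

```
src/trophdyn/
  traits.py       functional groups, biomass conversion, body-mass model
  covariates.py   anomalies, interpolation, lagging, standardization
  model.py        Poisson-link delta-Gamma JDSDM + Laplace fitting
  inference.py    adjusted CIs, exceedance probabilities, lag comparison
  synth.py        synthetic landscapes, fields and observations
  pipeline.py     end-to-end orchestration and fixture scenarios
  cli.py          command-line interface
docs/methods.md   model, assumptions, numerical choices, limitations
```
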