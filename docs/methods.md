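# Methods

`trophdyn` estimates bottom-up trophic effects of moth abundance on
forest-bird abundance from long-term monitoring data: light-trap moth
counts, breeding-bird point counts and line-transect habitat strips, and
breeding-season climate series. Species are pooled into functional
groups — birds by migratory strategy crossed with reliance on
caterpillars when provisioning nestlings (11 populated combinations),
moths by overwintering stage (larva, adult/egg, pupa) after restricting
the analysis to species whose caterpillars are "easy" prey. The
question the model answers is whether the previous year's prey biomass
anomaly predicts this year's predator biomass density.

## Observation model

Group biomass `B(s, c, t)` at site `s`, group `c`, year `t` follows a
hurdle (delta) distribution: a point mass `1 - r1` at zero and, given
occurrence, a Gamma distribution with mean `r2` and coefficient of
variation `sigma_m(c)` (shape `1/sigma_m^2`, scale `r2 sigma_m^2`).
Occurrence and conditional biomass are not free parameters but are
derived from an underlying number density `n = exp(p1)` and mean body
mass `w = exp(p2)` through the Poisson link,

    r1 = 1 - exp(-a n),      r2 = a n w / r1,

with `a` the site's effective sampled area. The identity
`r1 r2 = a n w` holds by construction, which is what makes covariate
effects interpretable on the density scale: a coefficient on `p1` is a
log-linear effect on expected biomass density `d = n w`. This
construction closely approximates a compound-Poisson (Tweedie) biomass
distribution: if species counts are Poisson with total intensity `a n`
and individuals carry mass `w`, the zero probability is exactly
`exp(-a n)` and the conditional mean is exactly `r2`. The fixture
generator for the pipeline exploits this: it draws species-level
breeding-pair counts as Poissons, so the pooled biomass matches the
fitted model's zero pattern and mean without circularity, while the
model-level generator draws from the delta-Gamma itself.

## Linear predictors and latent structure

Both predictors contain group intercepts, standardized covariate
effects, factor-analytic spatial and spatio-temporal Gaussian fields,
census-route overdispersion and a census-type (point vs strip) fixed
effect with "point" as the reference level:

    p1(s,c,t) = beta1(c,t) + sum_k gamma1(c,k) X(s,t,k)
                + [L_omega1 psi(s)]_c + [L_eps1 phi(s,t)]_c
                + eta1(route(s), c) + delta1(type(s), c)

and analogously for `p2`. Factor fields `psi`, `phi` have unit marginal
variance and Matern covariance with smoothness fixed at 1 (the standard
SPDE-type choice; smoothness is not identifiable from these data) and a
shared estimated range. Spatio-temporal factors are independent across
years; temporal persistence enters through the density-predictor
intercepts `beta1(c, t)`, which follow a stationary AR1 process around a
group mean with estimated correlation and innovation standard
deviation. Intercepts on the body-mass predictor are either constant
per group or independent year effects (configurable; constant is the
default in the scaled study conditions, iid in the full model).

Identifiability: loading matrices are lower-triangular; the number of
factors per field type is configurable (default 2, capped at the number
of groups) because the appropriate rank is an empirical choice the data
rarely pin down.

## Estimation

Latent fields, AR1 intercept deviations, iid year effects and
overdispersion terms are random effects; everything else is fixed. The
marginal likelihood integrates the joint likelihood over the random
effects with a Laplace approximation: a damped Newton iteration finds
the joint-likelihood mode in the random effects (gradient max-norm
below 1e-8), and the marginal negative log-likelihood is the joint
value at the mode plus half the log-determinant of the inner Hessian.
The observation model's gradient and Hessian with respect to `(p1, p2)`
are closed form and verified against finite differences in the test
suite; the inner Hessian is assembled from sparse per-row Jacobians
plus the block prior precision (Matern inverses, AR1 tridiagonals,
diagonal iid blocks).

The outer optimization over fixed effects uses L-BFGS with
finite-difference gradients on a transformed scale (log for standard
deviations, dispersions and the Matern range; inverse hyperbolic
tangent for the AR1 correlation). Because the outer gradient is itself
a finite difference, its noise floor is above what an analytic gradient
would give; the convergence criterion is a gradient max-norm of 5e-3
(configurable), which on the scenarios in this package corresponds to
parameter movements far below the Monte-Carlo noise of the estimates.
The fixed-effect covariance is the inverse of a central-difference
Hessian of the marginal objective (step 1e-4), mapped back to the
natural scale by the chain rule; standard errors of derived quantities
use the delta method. If the finite-difference Hessian is not positive
definite it is recomputed with a tenfold coarser step (curvature noise
is the usual cause); if a flat direction remains, its eigenvalue is
clipped to a small positive floor with a warning, so the affected
standard errors are large lower bounds on the uncertainty rather than
spurious zeros. A fit whose measured gradient norm exceeds the
tolerance is flagged, never silently reported as converged.

For site sets larger than `max_sites` (default 300) the fields are
defined on k-means anchor sites and interpolated to observation sites
with k-nearest inverse-distance weights — an inducing-point
approximation that bounds the cost of the dense Matern algebra.

Numerical choices: linear predictors are clipped at |40| far from the
optimum to keep exponentials finite; Cholesky factorizations retry with
escalating diagonal jitter before raising; Gamma shape is `1/sigma_m^2`
so `sigma_m` is directly the conditional coefficient of variation.
Initialization is data-driven (occurrence frequency inverted through
the link for density intercepts, positive-mean matching for body-mass
intercepts), with loadings at 0.3 on the diagonal pattern and a small
seed-controlled jitter.

## Covariate construction

Per-trap annual moth-group biomass becomes an ln-anomaly:
`ln(B + eps) - mean_year ln(B + eps)` with `eps = 1 mg` so empty years
stay finite; centring within trap cancels trap-effort differences.
Anomalies are interpolated to bird sites by inverse-distance weighting
with power 2 (a Gaussian-kernel alternative is selectable); the
interpolation is validated by leave-one-trap-out correlation between
observed and predicted anomalies, reported overall and per group.
Climate covariates are per-site anomalies of May-June mean temperature
and precipitation sum relative to a reference period. All covariates
attach to the response with a one-year lag by default (prey abundance
and breeding-season weather in year t-1 drive predator abundance in
year t) and are standardized to zero mean and unit variance over the
analysed rows, so effects are comparable across covariates. The lag is
itself checked by refitting at candidate lags and comparing marginal
AIC.

## Effect assessment

Wald intervals use a Bonferroni-adjusted confidence level
`1 - alpha / (n_predictors x n_groups)`; with alpha 0.05, two linear
predictors and 11 bird groups this is the 99.8% level (per-test alpha
0.002). For clusters of large-but-not-significant effects, the
package computes the probability of observing at least `k` effects with
absolute size at or above a threshold within a family of comparisons:
the single-effect tail probability comes from the empirical CDF of all
estimated effects, and the family probability is a binomial tail
(default) or a Monte-Carlo resample from the empirical distribution;
the two agree within Monte-Carlo error and the resampling route serves
as the cross-check of the binomial default.

## Synthetic data and study conditions

The generator is the model's generative twin: uniform random site
coordinates over a square landscape (default 300 km), point and strip
census types (strip area offsets drawn log-normally), traps on the same
landscape so interpolation accuracy is controllable through trap
density, Matern(1) fields drawn by Cholesky, stationary AR1 intercepts,
and delta-Gamma observations through the Poisson link. Specimen tables
for the body-mass regression and correlated climate series are also
generated. Scenario defaults were chosen once as representative of
boreal monitoring data: occurrence probabilities mostly between 0.4 and
0.8, Gamma CV 0.8, AR1 correlation 0.5 with innovation sd 0.3, spatial
loadings 0.25-0.5, Matern range 60 km, covariate effect 0.4 (0.5 in the
strong-coupling pipeline scenario, 0 in the null).

The standard recovery conditions are 100 sites, 15 years, 3 functional
groups and 10 replicate fits; the null (type-I) conditions are 60
sites, 10 years, 3 covariates, 20 replicates; the lag study uses 40
sites, 10 years and 10 replicates over candidate lags 0-2. In these
scaled scenarios the truth contains a spatial factor and AR1 intercepts
but no spatio-temporal factor, and the fit is configured to match; the
spatio-temporal machinery (and overdispersion, iid year effects, fields
on the body-mass predictor) is exercised by its own tests at smaller
size. What the generator does not emulate: real geography and
projection effects, within-season phenology, detection differences
among species within a group, trait misclassification, and
non-stationary trends. Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to the violations real monitoring data contain.

## Known limitations

- Finite-difference outer gradients make fitting slower and the
  gradient-norm stopping rule coarser than an autodiff implementation;
  the chosen tolerances are calibrated to the package's scenario sizes.
- The exceedance-probability family definition (which effects form the
  family, and which pool defines the empirical CDF) is configurable
  because the construction admits several reasonable choices; the
  default is the binomial tail over one region-by-moth-group family
  with the tail probability pooled across all estimated effects.
- Deviance explained uses each fit's own dispersion estimates in its
  saturated reference; comparisons are between nested fits on the same
  data.
- The anchor-site reduction trades spatial resolution for tractability
  above 300 sites; range estimates shrink-bias slightly when the anchor
  grid is much coarser than the true range.
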