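"""Synthetic landscapes, latent fields and survey observations.

Generative twin of the fitted model: sites on a planar landscape (km),
zero-mean Matern (smoothness 1) Gaussian factor fields with unit
marginal variance, stationary AR1 group-by-year intercepts, and
Poisson-link delta-Gamma biomass observations.  Every generator is a
pure function of its arguments (seed included), so downstream stages are
testable with known ground truth and no data download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.spatial.distance import pdist, squareform

from .errors import AlignmentError, ValidationError
from .model import matern_correlation, poisson_link, sample_delta_gamma

REGIONS = ("NB", "MB", "SB")


@dataclass
class TruthParams:
    """Known generative parameters of a synthetic scenario.

    ``intercept_mean`` (per group) is the mean of the log number-density
    predictor; ``covariate_effects`` is group x covariate on that same
    predictor; loadings are lower-triangular group x factor matrices;
    ``gamma_cv`` is the coefficient of variation of positive biomass;
    ``log_mass`` sets the (constant) body-mass predictor per group;
    ``lag`` is the year offset between the covariate source series and
    the biomass response.
    """

    intercept_mean: np.ndarray
    ar1_rho: float = 0.5
    ar1_sd: float = 0.3
    covariate_effects: np.ndarray = field(default_factory=lambda: np.zeros((1, 0)))
    spatial_loadings: np.ndarray = field(default_factory=lambda: np.zeros((1, 0)))
    spatiotemporal_loadings: np.ndarray = field(
        default_factory=lambda: np.zeros((1, 0))
    )
    matern_range_km: float = 60.0
    gamma_cv: float = 0.8
    overdispersion_sd: float = 0.0
    lag: int = 1
    log_mass: np.ndarray | None = None

    def __post_init__(self):
        self.intercept_mean = np.atleast_1d(np.asarray(self.intercept_mean, float))
        G = len(self.intercept_mean)
        self.covariate_effects = np.asarray(self.covariate_effects, float).reshape(G, -1)
        self.spatial_loadings = np.asarray(self.spatial_loadings, float).reshape(G, -1)
        self.spatiotemporal_loadings = np.asarray(
            self.spatiotemporal_loadings, float
        ).reshape(G, -1)
        if self.log_mass is None:
            self.log_mass = np.zeros(G)
        self.log_mass = np.atleast_1d(np.asarray(self.log_mass, float))
        if not -1 < self.ar1_rho < 1:
            raise ValidationError("ar1_rho must lie in (-1, 1)")
        if self.ar1_sd < 0 or self.overdispersion_sd < 0:
            raise ValidationError("standard deviations must be non-negative")
        if self.matern_range_km <= 0 or self.gamma_cv <= 0:
            raise ValidationError("range and gamma_cv must be positive")
        if self.lag < 0 or int(self.lag) != self.lag:
            raise ValidationError("lag must be a non-negative integer")
        for L in (self.spatial_loadings, self.spatiotemporal_loadings):
            if L.shape[1] and not np.allclose(L, np.tril(L)):
                raise ValidationError("loading matrices must be lower-triangular")

    @property
    def n_groups(self):
        return len(self.intercept_mean)


@dataclass
class LatentFields:
    """Realized latent variables of one simulation."""

    spatial: np.ndarray  # (S, F_sp), unit marginal variance per factor
    spatiotemporal: np.ndarray  # (S, F_st, T), independent across years
    year_intercepts: np.ndarray  # (G, T), stationary AR1 around the mean


def make_sites(
    n_bird_sites: int, n_traps: int, region: str = "NB",
    extent_km: float = 300.0, seed: int = 0, route_size: int = 10,
) -> pd.DataFrame:
    """Random landscape of bird survey sites and moth light-traps.

    Bird sites alternate between point-count stations (area offset 1)
    and line-transect habitat strips (area offset proportional to a
    drawn strip length); traps get census_type "trap".  Sites are
    grouped into census routes of ``route_size`` for overdispersion.
    """
    if n_bird_sites < 1 or n_traps < 1:
        raise ValidationError("need at least one bird site and one trap")
    if extent_km <= 0:
        raise ValidationError("extent must be positive")
    if region not in REGIONS:
        raise ValidationError(f"region must be one of {REGIONS}")
    rng = np.random.default_rng(seed)
    n = n_bird_sites + n_traps
    xy = rng.uniform(0.0, extent_km, size=(n, 2))
    rows = []
    for i in range(n_bird_sites):
        is_point = i % 2 == 0
        rows.append({
            "site_id": f"{region}-b{i:04d}",
            "x": xy[i, 0], "y": xy[i, 1],
            "region": region,
            "census_type": "point" if is_point else "strip",
            "area_offset": 1.0 if is_point else float(
                np.clip(rng.lognormal(0.0, 0.3), 0.3, 3.0)
            ),
            "route_id": f"{region}-r{i // route_size:03d}",
        })
    for j in range(n_traps):
        i = n_bird_sites + j
        rows.append({
            "site_id": f"{region}-t{j:03d}",
            "x": xy[i, 0], "y": xy[i, 1],
            "region": region,
            "census_type": "trap",
            "area_offset": 1.0,
            "route_id": f"{region}-trap{j:03d}",
        })
    return pd.DataFrame(rows)


def bird_sites(sites: pd.DataFrame) -> pd.DataFrame:
    return sites[sites["census_type"] != "trap"].reset_index(drop=True)


def trap_sites(sites: pd.DataFrame) -> pd.DataFrame:
    return sites[sites["census_type"] == "trap"].reset_index(drop=True)


def _gp_draws(coords, range_km, n_draws, rng, jitter=1e-8):
    """Independent unit-variance Matern(nu=1) field draws, (S, n_draws)."""
    D = squareform(pdist(coords))
    C = matern_correlation(D, range_km) + jitter * np.eye(len(coords))
    L = cholesky(C, lower=True)
    return L @ rng.standard_normal((len(coords), n_draws))


def simulate_ar1(mean, rho, sd, T, rng):
    """Stationary AR1 path(s) around ``mean``; innovation sd ``sd``."""
    mean = np.atleast_1d(np.asarray(mean, float))
    G = len(mean)
    x = np.empty((G, T))
    marg = sd / np.sqrt(1.0 - rho**2) if sd > 0 else 0.0
    x[:, 0] = mean + marg * rng.standard_normal(G)
    for t in range(1, T):
        x[:, t] = mean + rho * (x[:, t - 1] - mean) + sd * rng.standard_normal(G)
    return x


def simulate_latent_fields(
    sites: pd.DataFrame, years: int, truth: TruthParams, seed: int = 0
) -> LatentFields:
    """Draw spatial/spatio-temporal factor fields and AR1 intercepts."""
    if years < 2:
        raise ValidationError("need at least 2 years")
    rng = np.random.default_rng(seed)
    coords = sites[["x", "y"]].to_numpy(float)
    S = len(coords)
    Fsp = truth.spatial_loadings.shape[1]
    Fst = truth.spatiotemporal_loadings.shape[1]
    spatial = (
        _gp_draws(coords, truth.matern_range_km, Fsp, rng)
        if Fsp else np.zeros((S, 0))
    )
    if Fst:
        st = _gp_draws(coords, truth.matern_range_km, Fst * years, rng)
        spatiotemporal = st.reshape(S, years, Fst).transpose(0, 2, 1)
    else:
        spatiotemporal = np.zeros((S, 0, years))
    year_intercepts = simulate_ar1(
        truth.intercept_mean, truth.ar1_rho, truth.ar1_sd, years, rng
    )
    return LatentFields(spatial, spatiotemporal, year_intercepts)


def _covariate_array(covariates, site_ids, years_labels, K):
    """Align a long covariate frame to (S, T, K); error on missing keys."""
    if K == 0:
        return np.zeros((len(site_ids), len(years_labels), 0))
    piv = covariates.pivot_table(
        index=["site_id", "year"], columns="covariate", values="value"
    )
    names = sorted(covariates["covariate"].unique())
    X = np.empty((len(site_ids), len(years_labels), K))
    for i, s in enumerate(site_ids):
        for j, t in enumerate(years_labels):
            try:
                X[i, j] = piv.loc[(s, t), names].to_numpy(float)
            except KeyError:
                raise AlignmentError(
                    f"covariate design missing site {s!r}, year {t}"
                ) from None
    if np.isnan(X).any():
        raise AlignmentError("covariate design contains missing values")
    return X


def simulate_observations(
    sites: pd.DataFrame,
    fields: LatentFields,
    covariates: pd.DataFrame | None,
    truth: TruthParams,
    seed: int = 0,
    years_labels=None,
    group_names=None,
) -> pd.DataFrame:
    """Poisson-link delta-Gamma biomass observations at bird sites.

    For each site/group/year the density predictor is assembled from the
    AR1 intercept, covariate effects, loaded factor fields and (optional)
    route overdispersion; the Poisson link maps (n, w) to (r1, r2);
    occurrence is Bernoulli(r1) and positive biomass Gamma with mean r2
    and coefficient of variation ``truth.gamma_cv``.  Zeros are explicit
    rows.
    """
    rng = np.random.default_rng(seed)
    birds = bird_sites(sites)
    all_ids = sites["site_id"].tolist()
    site_row = {s: i for i, s in enumerate(all_ids)}
    G = truth.n_groups
    T = fields.year_intercepts.shape[1]
    years_labels = list(range(T)) if years_labels is None else list(years_labels)
    if len(years_labels) != T:
        raise ValidationError("years_labels length must match the fields")
    if group_names is None:
        group_names = [f"G{c+1}" for c in range(G)]
    K = truth.covariate_effects.shape[1]
    X = (
        _covariate_array(covariates, birds["site_id"].tolist(), years_labels, K)
        if K else np.zeros((len(birds), T, 0))
    )

    routes = sorted(birds["route_id"].unique())
    eta = (
        truth.overdispersion_sd * rng.standard_normal((len(routes), G))
        if truth.overdispersion_sd > 0 else np.zeros((len(routes), G))
    )
    route_pos = {r: i for i, r in enumerate(routes)}

    recs = []
    for bi, row in birds.iterrows():
        si = site_row[row["site_id"]]
        for c in range(G):
            p1 = (
                fields.year_intercepts[c, :]
                + X[bi] @ truth.covariate_effects[c]
                + fields.spatial[si] @ truth.spatial_loadings[c]
                + truth.spatiotemporal_loadings[c] @ fields.spatiotemporal[si]
                + eta[route_pos[row["route_id"]], c]
            )
            n = np.exp(p1)
            w = np.exp(truth.log_mass[c])
            r1, r2 = poisson_link(n, w, row["area_offset"])
            B = sample_delta_gamma(r1, np.maximum(r2, 1e-300), truth.gamma_cv, rng)
            for j, t in enumerate(years_labels):
                recs.append({
                    "site_id": row["site_id"], "year": t,
                    "group_id": group_names[c], "biomass": B[j],
                })
    return pd.DataFrame(recs)


def simulate_specimens(
    n: int,
    true_coefs=(5.0, 2.5, 30.0),
    noise_sd: float = 5.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Specimen table (species, wingspan, body plan, fresh mass).

    ``true_coefs`` = (intercept mg, wingspan slope mg/mm, stout offset mg).
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if n < 3:
        raise ValidationError("need at least 3 specimens (underdetermined design)")
    rng = np.random.default_rng(seed)
    b0, b1, b2 = true_coefs
    wingspan = rng.uniform(8.0, 60.0, n)
    stout = rng.integers(0, 2, n)
    # force both body plans so the full design is identifiable
    stout[0], stout[1] = 0, 1
    mass = b0 + b1 * wingspan + b2 * stout + noise_sd * rng.standard_normal(n)
    return pd.DataFrame({
        "species_id": [f"sp{i:04d}" for i in range(n)],
        "wingspan_mm": wingspan,
        "body_plan": np.where(stout == 1, "stout", "slender"),
        "mass_mg": mass,
    })


def simulate_climate(
    sites: pd.DataFrame,
    years,
    seed: int = 0,
    temp_year_sd: float = 1.2,
    temp_site_sd: float = 0.7,
    temp_noise_sd: float = 0.4,
    precip_year_sd: float = 25.0,
    precip_site_sd: float = 15.0,
    precip_noise_sd: float = 10.0,
) -> pd.DataFrame:
    """May-June mean temperature and precipitation sum per site/year.

    Year-level shocks are shared across sites (so nearby sites are
    positively correlated by construction) on top of site-level means
    and independent noise.
    """
    if np.isscalar(years):
        years = list(range(int(years)))
    years = list(years)
    if len(years) < 2:
        raise ValidationError("need at least 2 years")
    rng = np.random.default_rng(seed)
    ids = sites["site_id"].tolist()
    t_site = temp_site_sd * rng.standard_normal(len(ids))
    p_site = precip_site_sd * rng.standard_normal(len(ids))
    t_year = temp_year_sd * rng.standard_normal(len(years))
    p_year = precip_year_sd * rng.standard_normal(len(years))
    rows = []
    for i, s in enumerate(ids):
        for j, t in enumerate(years):
            rows.append({
                "site_id": s, "year": t,
                "temperature": 12.0 + t_site[i] + t_year[j]
                + temp_noise_sd * rng.standard_normal(),
                "precipitation": 120.0 + p_site[i] + p_year[j]
                + precip_noise_sd * rng.standard_normal(),
            })
    return pd.DataFrame(rows)


def simulate_anomaly_covariates(
    sites: pd.DataFrame,
    years,
    names=("moth_anomaly",),
    range_km: float = 60.0,
    seed: int = 0,
    year_weight: float = 0.6,
    field_weight: float = 0.8,
    standardize: bool = True,
) -> pd.DataFrame:
    """Standardized anomaly-like covariate series at the given sites.

    Each covariate is a shared year shock plus an independent spatial
    Matern field per year, mimicking interpolated ln-anomalies after
    standardization.  Returns long rows (site_id, covariate, year,
    value).
    """
    if np.isscalar(years):
        years = list(range(int(years)))
    years = list(years)
    rng = np.random.default_rng(seed)
    coords = sites[["x", "y"]].to_numpy(float)
    frames = []
    for name in names:
        shocks = rng.standard_normal(len(years))
        fields_ = _gp_draws(coords, range_km, len(years), rng)
        vals = year_weight * shocks[None, :] + field_weight * fields_
        if standardize:
            vals = (vals - vals.mean()) / vals.std()
        frames.append(pd.DataFrame({
            "site_id": np.repeat(sites["site_id"].to_numpy(), len(years)),
            "covariate": name,
            "year": np.tile(years, len(sites)),
            "value": vals.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def lag_scenario(
    n_sites: int = 50,
    n_years: int = 10,
    n_groups: int = 3,
    effect: float = 0.4,
    true_lag: int = 1,
    seed: int = 0,
    extent_km: float = 300.0,
):
    """Scenario for the time-lag sensitivity study.

    An unlagged anomaly series is generated over the analysis years plus
    enough preceding years for candidate lags up to 3; biomass responds
    to the series at ``true_lag`` years before the observation.  Returns
    (biomass, bird site table, anomalies, analysis_years, truth).
    """
    from .covariates import lag_and_standardize

    sites = make_sites(n_sites, 1, "NB", extent_km, seed=seed)
    birds = bird_sites(sites)
    y0 = 2000
    analysis_years = list(range(y0, y0 + n_years))
    source_years = list(range(y0 - 3, y0 + n_years))
    anomalies = simulate_anomaly_covariates(
        birds, source_years, names=("moth_anomaly",), range_km=60.0,
        seed=seed + 1, standardize=False,
    )
    design_true = lag_and_standardize(anomalies, true_lag, analysis_years)
    base_load = np.array([0.5, 0.35, 0.25])
    truth = TruthParams(
        intercept_mean=np.linspace(-0.5, 0.3, n_groups),
        ar1_rho=0.5, ar1_sd=0.3,
        covariate_effects=np.full((n_groups, 1), effect),
        spatial_loadings=np.resize(base_load, n_groups).reshape(n_groups, 1),
        spatiotemporal_loadings=np.zeros((n_groups, 0)),
        matern_range_km=60.0, gamma_cv=0.8, lag=true_lag,
        log_mass=np.full(n_groups, 1.5),
    )
    fields = simulate_latent_fields(sites, n_years, truth, seed=seed + 2)
    biomass = simulate_observations(
        sites, fields, design_true, truth, seed=seed + 3,
        years_labels=analysis_years,
    )
    return biomass, birds, anomalies, analysis_years, truth


def recovery_scenario(
    n_sites: int = 100,
    n_years: int = 15,
    n_groups: int = 3,
    effect: float = 0.4,
    n_covariates: int = 1,
    seed: int = 0,
    extent_km: float = 300.0,
):
    """Standard parameter-recovery study conditions.

    Landscape of point/strip bird sites; truth: AR1 intercepts
    (rho 0.5, innovation sd 0.3), one spatial factor with loadings
    0.5/0.35/0.25, no spatio-temporal factor, Matern range 60 km, Gamma
    CV 0.8, and the given covariate effect on every group x covariate
    cell of the density predictor.  Returns (biomass, sites, design,
    truth).
    """
    rng_seed = int(seed)
    sites = make_sites(n_sites, 1, "NB", extent_km, seed=rng_seed)
    birds = bird_sites(sites)
    base_load = np.array([0.5, 0.35, 0.25])
    loadings = np.resize(base_load, n_groups).reshape(n_groups, 1)
    truth = TruthParams(
        intercept_mean=np.linspace(-0.5, 0.3, n_groups),
        ar1_rho=0.5,
        ar1_sd=0.3,
        covariate_effects=np.full((n_groups, n_covariates), effect),
        spatial_loadings=loadings,
        spatiotemporal_loadings=np.zeros((n_groups, 0)),
        matern_range_km=60.0,
        gamma_cv=0.8,
        log_mass=np.full(n_groups, 1.5),
    )
    years = list(range(2000, 2000 + n_years))
    design = simulate_anomaly_covariates(
        birds, years,
        names=[f"x{k+1}" for k in range(n_covariates)],
        range_km=60.0, seed=rng_seed + 1,
    )
    fields = simulate_latent_fields(sites, n_years, truth, seed=rng_seed + 2)
    biomass = simulate_observations(
        sites, fields, design, truth, seed=rng_seed + 3,
        years_labels=years,
    )
    return biomass, birds, design, truth
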