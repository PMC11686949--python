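"""Poisson-link delta-Gamma joint dynamic species distribution model.

The biomass ``B`` of functional group ``c`` at site ``s`` in year ``t``
follows a two-part (hurdle) distribution:

    Pr[B = 0]     = 1 - r1
    Pr[B | B > 0] = Gamma(mean r2, coefficient of variation sigma_m)

where occurrence probability ``r1`` and conditional biomass ``r2`` are
tied to an underlying number density ``n`` and mean body mass ``w``
through the Poisson link (``a`` is the effective sampled area):

    r1 = 1 - exp(-a n),    r2 = a n w / r1,    so  r1 r2 = a n w.

``n = exp(p1)`` and ``w = exp(p2)`` are modelled by two linear
predictors, each containing group intercepts, covariate effects,
factor-analytic spatial and spatio-temporal Gaussian fields (Matern
smoothness 1), census-route overdispersion and census-type effects.  The
density-predictor intercepts follow a stationary AR1 process over years.
Latent fields and random intercept deviations are integrated out by a
Laplace approximation; fixed effects maximize the resulting marginal
likelihood.

No automatic differentiation is used: the observation model's gradient
and Hessian with respect to (p1, p2) are closed form (verified against
finite differences in the test suite), the inner mode is found by a
damped Newton iteration, and the outer optimization uses
finite-difference gradients.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import approx_fprime, minimize
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.special import gammainc, gammaln, kv
from scipy.stats import gamma as gamma_dist

from .errors import AlignmentError, ConvergenceError, NumericalError, ValidationError

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_PRED_CLIP = 40.0  # |linear predictor| cap to keep exp() finite far from optimum


# --------------------------------------------------------------------------
# elementary building blocks
# --------------------------------------------------------------------------

def poisson_link(n, w, area_offset=1.0):
    """Map density ``n`` and mean body mass ``w`` to (r1, r2).

    r1 = 1 - exp(-a n); r2 = a n w / r1.  At n = 0 the limit gives
    r1 = 0, r2 = w.  The identity r1 * r2 = a * n * w holds exactly.
    """
    n = np.asarray(n, dtype=float)
    w = np.asarray(w, dtype=float)
    a = np.asarray(area_offset, dtype=float)
    if np.any(n < 0):
        raise ValidationError("density n must be non-negative")
    if np.any(w <= 0) or np.any(a <= 0):
        raise ValidationError("body mass and area offset must be positive")
    an = a * n
    r1 = -np.expm1(-an)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(an > 0, an / np.where(r1 > 0, r1, 1.0), 1.0)
    r2 = ratio * w
    return r1, r2


def delta_gamma_logpdf(B, r1, r2, sigma_m):
    """Log-density of the zero-inflated Gamma mixture.

    Point mass 1 - r1 at zero; for B > 0, r1 times a Gamma density with
    mean r2 and coefficient of variation sigma_m (shape k = 1/sigma_m^2,
    scale r2 sigma_m^2).
    """
    B = np.asarray(B, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    sigma_m = np.asarray(sigma_m, dtype=float)
    if np.any(B < 0):
        raise ValidationError("biomass must be non-negative")
    if np.any((r1 < 0) | (r1 > 1)):
        raise ValidationError("r1 must lie in [0, 1]")
    if np.any(r2 <= 0) or np.any(sigma_m <= 0):
        raise ValidationError("r2 and sigma_m must be positive")
    B, r1, r2, sigma_m = np.broadcast_arrays(B, r1, r2, sigma_m)
    k = 1.0 / sigma_m**2
    out = np.empty_like(B, dtype=float)
    zero = B == 0
    with np.errstate(divide="ignore"):
        out[zero] = np.log1p(-r1[zero])
        pos = ~zero
        scale = r2[pos] / k[pos]
        out[pos] = (
            np.log(r1[pos])
            + (k[pos] - 1) * np.log(B[pos])
            - B[pos] / scale
            - k[pos] * np.log(scale)
            - gammaln(k[pos])
        )
    return out


def matern_correlation(dists, range_km):
    """Matern correlation, smoothness nu = 1, unit variance.

    C(d) = (sqrt(2) d / range) * K_1(sqrt(2) d / range), C(0) = 1.
    """
    if range_km <= 0:
        raise ValidationError("range must be positive")
    d = np.asarray(dists, dtype=float)
    arg = np.sqrt(2.0) * d / range_km
    out = np.ones_like(arg)
    pos = arg > 0
    with np.errstate(invalid="ignore"):
        out[pos] = arg[pos] * kv(1, arg[pos])
    out[~np.isfinite(out)] = 0.0  # kv underflow at large distance
    return out


def matern_covariance(dists, range_km, jitter=1e-8):
    """Matern(nu=1) correlation matrix with diagonal jitter.

    ``dists`` must be a symmetric matrix with zero diagonal.
    """
    d = np.asarray(dists, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValidationError("distances must be symmetric with zero diagonal")
    C = matern_correlation(d, range_km)
    return C + jitter * np.eye(len(C))


def _chol_jitter(M, jitter0, what="matrix"):
    """Cholesky with escalating diagonal jitter; raises NumericalError."""
    j = 0.0
    for _ in range(8):
        try:
            c = cho_factor(M + j * np.eye(len(M)), lower=True)
            return c, j
        except np.linalg.LinAlgError:
            j = jitter0 if j == 0.0 else j * 10.0
    diag = np.diag(M)
    raise NumericalError(
        f"Cholesky of {what} failed after jitter escalation to {j:.1e} "
        f"(diag range [{diag.min():.3g}, {diag.max():.3g}], size {len(M)})"
    )


def _ar1_precision(T, rho, sd):
    """Precision matrix of a stationary AR1 with innovation sd."""
    if not abs(rho) < 1:
        raise ValidationError("|rho| must be < 1")
    if sd <= 0:
        raise ValidationError("AR1 innovation sd must be positive")
    if T == 1:
        return np.array([[(1 - rho**2) / sd**2]])
    M = np.zeros((T, T))
    idx = np.arange(T)
    M[idx, idx] = 1 + rho**2
    M[0, 0] = M[-1, -1] = 1.0
    M[idx[:-1], idx[1:]] = -rho
    M[idx[1:], idx[:-1]] = -rho
    return M / sd**2


def ar1_logdensity(x, mean, rho, sd):
    """Stationary AR1 Gaussian log-density of a year sequence."""
    x = np.asarray(x, dtype=float)
    T = x.size
    Q = _ar1_precision(T, rho, sd)
    dev = x - mean
    logdet_sigma = T * np.log(sd**2) - np.log1p(-rho**2)
    return float(-0.5 * (dev @ Q @ dev + logdet_sigma + T * _LOG2PI))


def _obs_loglik_derivs(B, p1, p2, loga, k, want_derivs=True):
    """Row-wise log-likelihood and derivatives w.r.t. (p1, p2).

    Returns (ll, g1, g2, h11, h12, h22); derivative arrays are None when
    ``want_derivs`` is False.  ``k`` is the Gamma shape per row.
    """
    eta1 = np.clip(p1 + loga, -_PRED_CLIP, _PRED_CLIP)
    p2c = np.clip(p2, -_PRED_CLIP, _PRED_CLIP)
    mu = np.exp(eta1)  # a * n
    zero = B == 0

    ll = np.empty_like(mu)
    ll[zero] = -mu[zero]

    em = np.exp(-mu)
    r1 = -np.expm1(-mu)
    pos = ~zero
    logr1 = np.log(r1[pos])
    h = mu[pos] * em[pos] / r1[pos]
    logr2 = eta1[pos] + p2c[pos] - logr1
    q = B[pos] * np.exp(-logr2)  # B / r2
    kp = k[pos]
    ll[pos] = (
        logr1
        + kp * np.log(kp)
        - kp * logr2
        - gammaln(kp)
        + (kp - 1) * np.log(B[pos])
        - kp * q
    )
    if not want_derivs:
        return ll, None, None, None, None, None

    g1 = np.empty_like(mu)
    g2 = np.zeros_like(mu)
    h11 = np.empty_like(mu)
    h12 = np.zeros_like(mu)
    h22 = np.zeros_like(mu)

    g1[zero] = -mu[zero]
    h11[zero] = -mu[zero]

    one_h = 1.0 - h
    qm1 = q - 1.0
    g1[pos] = h + kp * one_h * qm1
    g2[pos] = kp * qm1
    hp = h * (1.0 - mu[pos] / r1[pos])
    h11[pos] = hp + kp * (-hp * qm1 - q * one_h**2)
    h12[pos] = -kp * one_h * q
    h22[pos] = -kp * q
    return ll, g1, g2, h11, h12, h22


# --------------------------------------------------------------------------
# configuration and parameters
# --------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Structural and numerical configuration of the model fit.

    Factor counts apply to both linear predictors; the Matern smoothness
    is fixed at 1.  ``year_effects_2`` is "iid" (random year intercepts
    on the body-mass predictor) or "constant" (one intercept per group).
    """

    n_factors_spatial: int = 2
    n_factors_spatiotemporal: int = 2
    fields_on_predictor2: bool = True
    covariates_on_predictor2: bool = True
    year_effects_2: str = "iid"
    estimate_ar1: bool = True
    include_overdispersion: bool = False
    include_census_effects: bool = True
    outer_gtol: float = 5e-3
    inner_gtol: float = 1e-8
    max_outer_iter: int = 400
    max_inner_iter: int = 100
    jitter: float = 1e-8
    fd_eps: float = 1e-6
    hess_eps: float = 1e-4
    seed: int = 0
    compute_se: bool = True
    max_sites: int = 300
    n_anchor_sites: int = 100

    def __post_init__(self):
        if self.year_effects_2 not in ("iid", "constant"):
            raise ValidationError("year_effects_2 must be 'iid' or 'constant'")
        if self.n_factors_spatial < 0 or self.n_factors_spatiotemporal < 0:
            raise ValidationError("factor counts must be non-negative")


def _tril_indices(G, F):
    """(row, col) pairs of the lower triangle of a G x F loading matrix."""
    return [(c, f) for f in range(F) for c in range(f, G)]


def _loading_matrix(vec, G, F):
    L = np.zeros((G, F))
    for v, (c, f) in zip(vec, _tril_indices(G, F)):
        L[c, f] = v
    return L


class _ParamSpec:
    """Bookkeeping between natural parameters and the transformed vector.

    Transforms: 'id', 'log' (positives), 'atanh' (correlations).
    """

    def __init__(self, entries):
        self.entries = entries  # list of (name, size, transform)
        self.size = sum(e[1] for e in entries)
        self.slices = {}
        off = 0
        for name, n, _ in entries:
            self.slices[name] = slice(off, off + n)
            off += n

    def pack(self, natural: dict) -> np.ndarray:
        z = np.empty(self.size)
        for name, n, tf in self.entries:
            v = np.atleast_1d(np.asarray(natural[name], dtype=float)).ravel()
            if tf == "log":
                v = np.log(v)
            elif tf == "atanh":
                v = np.arctanh(v)
            z[self.slices[name]] = v
        return z

    def unpack(self, z: np.ndarray) -> dict:
        out = {}
        for name, n, tf in self.entries:
            v = np.array(z[self.slices[name]], dtype=float)
            if tf == "log":
                v = np.exp(np.clip(v, -30, 30))
            elif tf == "atanh":
                v = np.tanh(v)
            out[name] = v if n > 1 else float(v[0])
        return out

    def natural_jacobian_diag(self, z: np.ndarray) -> np.ndarray:
        """d(natural)/d(z), elementwise (the transforms are separable)."""
        J = np.ones(self.size)
        for name, n, tf in self.entries:
            sl = self.slices[name]
            if tf == "log":
                J[sl] = np.exp(np.clip(z[sl], -30, 30))
            elif tf == "atanh":
                J[sl] = 1.0 - np.tanh(z[sl]) ** 2
        return J

    def flat_names(self) -> list[str]:
        names = []
        for name, n, _ in self.entries:
            if n == 1:
                names.append(name)
            else:
                names.extend(f"{name}[{i}]" for i in range(n))
        return names


# --------------------------------------------------------------------------
# data container
# --------------------------------------------------------------------------

class FitData:
    """Aligned arrays for one model fit.

    Built from a group-biomass table (explicit zeros included), a site
    table and an optional covariate design.
    """

    def __init__(self, biomass_df, sites_df, design_df=None):
        req = {"site_id", "year", "group_id", "biomass"}
        if not req <= set(biomass_df.columns):
            raise ValidationError(f"biomass table needs columns {sorted(req)}")
        sreq = {"site_id", "x", "y", "census_type", "area_offset", "route_id"}
        if not sreq <= set(sites_df.columns):
            raise ValidationError(f"site table needs columns {sorted(sreq)}")
        if (biomass_df["biomass"] < 0).any():
            raise ValidationError("biomass must be non-negative")

        df = biomass_df.sort_values(
            ["site_id", "year", "group_id"], ignore_index=True
        )
        sites = sites_df.drop_duplicates("site_id").set_index("site_id")
        missing_sites = sorted(set(df["site_id"]) - set(sites.index))
        if missing_sites:
            raise AlignmentError(f"sites missing from site table: {missing_sites[:10]}")
        if (sites["area_offset"] <= 0).any():
            raise ValidationError("area offsets must be positive")

        self.site_ids = np.array(sorted(df["site_id"].unique()))
        self.groups = np.array(sorted(df["group_id"].unique()))
        self.years = np.array(sorted(df["year"].unique()))
        self.S, self.G, self.T = len(self.site_ids), len(self.groups), len(self.years)

        site_pos = {s: i for i, s in enumerate(self.site_ids)}
        group_pos = {g: i for i, g in enumerate(self.groups)}
        year_pos = {t: i for i, t in enumerate(self.years)}
        self.s_idx = df["site_id"].map(site_pos).to_numpy()
        self.c_idx = df["group_id"].map(group_pos).to_numpy()
        self.t_idx = df["year"].map(year_pos).to_numpy()
        self.B = df["biomass"].to_numpy(float)
        self.rows = df

        ordered = sites.loc[self.site_ids]
        self.coords = ordered[["x", "y"]].to_numpy(float)
        self.area = ordered["area_offset"].to_numpy(float)[self.s_idx]
        self.loga = np.log(self.area)

        routes = np.array(sorted(ordered["route_id"].unique()))
        route_pos = {r: i for i, r in enumerate(routes)}
        self.routes = routes
        self.n_routes = len(routes)
        self.route_idx = ordered["route_id"].map(route_pos).to_numpy()[self.s_idx]

        ctypes = sorted(ordered["census_type"].unique())
        if "point" in ctypes:  # reference level
            ctypes = ["point"] + [c for c in ctypes if c != "point"]
        self.census_types = ctypes
        ct_pos = {c: i for i, c in enumerate(ctypes)}
        self.cens_idx = ordered["census_type"].map(ct_pos).to_numpy()[self.s_idx]
        self.n_census = len(ctypes)

        if design_df is not None and len(design_df):
            covs = sorted(design_df["covariate"].unique())
            self.covariates = covs
            self.K = len(covs)
            piv = design_df.pivot_table(
                index=["site_id", "year"], columns="covariate", values="value"
            )
            try:
                X = piv.loc[
                    list(zip(df["site_id"], df["year"])), covs
                ].to_numpy(float)
            except KeyError as exc:
                raise AlignmentError(
                    f"covariate design missing site/year key: {exc}"
                ) from exc
            if np.isnan(X).any():
                bad = df.loc[np.isnan(X).any(axis=1), ["site_id", "year"]].iloc[0]
                raise AlignmentError(
                    f"covariate design incomplete at site {bad['site_id']!r}, "
                    f"year {bad['year']}"
                )
            self.X = X
        else:
            self.covariates = []
            self.K = 0
            self.X = np.zeros((len(df), 0))
        self.n_rows = len(df)


# --------------------------------------------------------------------------
# assembler: joint likelihood, Laplace approximation, fitting
# --------------------------------------------------------------------------

class _Assembler:
    """Precomputed index structure for fast joint NLL / Laplace evaluation."""

    def __init__(self, data: FitData, config: ModelConfig):
        self.data = data
        self.config = config
        G, S, T = data.G, data.S, data.T
        if config.n_factors_spatial > G or config.n_factors_spatiotemporal > G:
            raise ValidationError("factor counts must not exceed group count")

        self.Fsp = config.n_factors_spatial
        self.Fst = config.n_factors_spatiotemporal
        self.use2 = config.fields_on_predictor2
        self.iid2 = config.year_effects_2 == "iid"
        self.od = config.include_overdispersion
        self.cens = config.include_census_effects and data.n_census > 1

        # anchor (inducing-site) reduction for large site sets
        if S > config.max_sites:
            self.anchors, self.Wmap = self._make_anchors(config.n_anchor_sites)
        else:
            self.anchors = data.coords
            self.Wmap = None
        self.M = len(self.anchors)
        self.anchor_dists = squareform(pdist(self.anchors))

        self._build_param_spec()
        self._build_layout()
        self._build_jacobian_pattern()
        self._u_cache = np.zeros(self.n_u)
        self.n_evaluations = 0

    # -- structure ---------------------------------------------------------

    def _make_anchors(self, M):
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=M, n_init=3, random_state=0).fit(self.data.coords)
        anchors = km.cluster_centers_
        D = cdist(self.data.coords, anchors)
        k = min(5, M)
        W = np.zeros((self.data.S, M))
        for s in range(self.data.S):
            near = np.argsort(D[s])[:k]
            w = 1.0 / (D[s, near] + 1e-6)
            W[s, near] = w / w.sum()
        return anchors, W

    def _build_param_spec(self):
        d, c = self.data, self.config
        G, K = d.G, d.K
        ent = [("beta1_mean", G, "id")]
        if c.estimate_ar1:
            ent.append(("ar1_rho", 1, "atanh"))
        ent.append(("ar1_sd", 1, "log"))
        ent.append(("beta2_mean", G, "id"))
        if self.iid2:
            ent.append(("beta2_sd", 1, "log"))
        if K:
            ent.append(("gamma1", G * K, "id"))
            if c.covariates_on_predictor2:
                ent.append(("gamma2", G * K, "id"))
        if self.Fsp:
            n = len(_tril_indices(G, self.Fsp))
            ent.append(("L_omega1", n, "id"))
            if self.use2:
                ent.append(("L_omega2", n, "id"))
        if self.Fst:
            n = len(_tril_indices(G, self.Fst))
            ent.append(("L_eps1", n, "id"))
            if self.use2:
                ent.append(("L_eps2", n, "id"))
        if self.Fsp or self.Fst:
            ent.append(("range_km", 1, "log"))
        ent.append(("sigma_m", G, "log"))
        if self.od:
            ent.append(("od_sd1", 1, "log"))
            ent.append(("od_sd2", 1, "log"))
        if self.cens:
            n = (d.n_census - 1) * G
            ent.append(("census1", n, "id"))
            ent.append(("census2", n, "id"))
        self.spec = _ParamSpec(ent)

    def _build_layout(self):
        d = self.data
        G, T, M = d.G, d.T, self.M
        blocks = []
        if self.Fsp:
            blocks.append(("psi1", M * self.Fsp))
            if self.use2:
                blocks.append(("psi2", M * self.Fsp))
        if self.Fst:
            blocks.append(("phi1", M * T * self.Fst))
            if self.use2:
                blocks.append(("phi2", M * T * self.Fst))
        blocks.append(("db1", G * T))
        if self.iid2:
            blocks.append(("db2", G * T))
        if self.od:
            blocks.append(("eta1", d.n_routes * G))
            blocks.append(("eta2", d.n_routes * G))
        self.blocks = {}
        off = 0
        for name, n in blocks:
            self.blocks[name] = slice(off, off + n)
            off += n
        self.n_u = off

    def _field_cols(self, base, F, with_time):
        """u-columns touched by each data row for one field block."""
        d = self.data
        T = d.T
        if self.Wmap is None:
            # identity mapping: one anchor per site
            if with_time:
                cols = (
                    base
                    + (d.s_idx[:, None] * T + d.t_idx[:, None]) * F
                    + np.arange(F)[None, :]
                )
            else:
                cols = base + d.s_idx[:, None] * F + np.arange(F)[None, :]
            wts = np.ones_like(cols, dtype=float)
        else:
            # k-nearest anchors per site
            nz = [np.nonzero(self.Wmap[s])[0] for s in range(d.S)]
            kmax = max(len(z) for z in nz)
            anchor_ids = np.zeros((d.S, kmax), dtype=int)
            anchor_wts = np.zeros((d.S, kmax))
            for s, z in enumerate(nz):
                anchor_ids[s, : len(z)] = z
                anchor_wts[s, : len(z)] = self.Wmap[s, z]
            aid = anchor_ids[d.s_idx]  # (R, kmax)
            awt = anchor_wts[d.s_idx]
            if with_time:
                cols = (
                    base
                    + ((aid[:, :, None] * T + d.t_idx[:, None, None]) * F)
                    + np.arange(F)[None, None, :]
                ).reshape(d.n_rows, -1)
                wts = np.repeat(awt, F, axis=1)
            else:
                cols = (
                    base + aid[:, :, None] * F + np.arange(F)[None, None, :]
                ).reshape(d.n_rows, -1)
                wts = np.repeat(awt, F, axis=1)
        return cols, wts

    def _build_jacobian_pattern(self):
        """Column indices (fixed) for the sparse Jacobians dp/du."""
        d = self.data
        G, T = d.G, d.T
        self._cols1, self._base_wts1, self._kinds1 = [], [], []
        self._cols2, self._base_wts2, self._kinds2 = [], [], []

        db1 = self.blocks["db1"].start
        self._cols1.append((db1 + d.c_idx * T + d.t_idx)[:, None])
        self._base_wts1.append(np.ones((d.n_rows, 1)))
        self._kinds1.append(("const", None))
        if self.Fsp:
            cols, wts = self._field_cols(self.blocks["psi1"].start, self.Fsp, False)
            self._cols1.append(cols)
            self._base_wts1.append(wts)
            self._kinds1.append(("load", ("L_omega1", self.Fsp)))
        if self.Fst:
            cols, wts = self._field_cols(self.blocks["phi1"].start, self.Fst, True)
            self._cols1.append(cols)
            self._base_wts1.append(wts)
            self._kinds1.append(("load", ("L_eps1", self.Fst)))
        if self.od:
            e1 = self.blocks["eta1"].start
            self._cols1.append((e1 + d.route_idx * G + d.c_idx)[:, None])
            self._base_wts1.append(np.ones((d.n_rows, 1)))
            self._kinds1.append(("const", None))

        if self.iid2:
            db2 = self.blocks["db2"].start
            self._cols2.append((db2 + d.c_idx * T + d.t_idx)[:, None])
            self._base_wts2.append(np.ones((d.n_rows, 1)))
            self._kinds2.append(("const", None))
        if self.use2 and self.Fsp:
            cols, wts = self._field_cols(self.blocks["psi2"].start, self.Fsp, False)
            self._cols2.append(cols)
            self._base_wts2.append(wts)
            self._kinds2.append(("load", ("L_omega2", self.Fsp)))
        if self.use2 and self.Fst:
            cols, wts = self._field_cols(self.blocks["phi2"].start, self.Fst, True)
            self._cols2.append(cols)
            self._base_wts2.append(wts)
            self._kinds2.append(("load", ("L_eps2", self.Fst)))
        if self.od:
            e2 = self.blocks["eta2"].start
            self._cols2.append((e2 + d.route_idx * G + d.c_idx)[:, None])
            self._base_wts2.append(np.ones((d.n_rows, 1)))
            self._kinds2.append(("const", None))

    # -- per-evaluation preparation ---------------------------------------

    def _loading(self, nat, name, F):
        return _loading_matrix(np.atleast_1d(nat[name]), self.data.G, F)

    def _jacobian(self, cols_list, wts_list, kinds, nat):
        d = self.data
        if not cols_list:
            return sp.csr_matrix((d.n_rows, self.n_u))
        vals = []
        for (kind, info), base in zip(kinds, wts_list):
            if kind == "const":
                vals.append(base)
            else:
                name, F = info
                L = self._loading(nat, name, F)  # (G, F)
                per_row = L[d.c_idx]  # (R, F)
                if base.shape[1] == F:
                    vals.append(base * per_row)
                else:  # anchor expansion: base is (R, k*F) with F fastest
                    kk = base.shape[1] // F
                    vals.append(base * np.tile(per_row, (1, kk)))
        cols = np.concatenate(cols_list, axis=1)
        vals = np.concatenate(vals, axis=1)
        rows = np.repeat(np.arange(d.n_rows), cols.shape[1])
        A = sp.csr_matrix(
            (vals.ravel(), (rows, cols.ravel())), shape=(d.n_rows, self.n_u)
        )
        return A

    def prepare(self, nat: dict):
        """Per-evaluation quantities: offsets, Jacobians, prior precision."""
        d, c = self.data, self.config
        G, T, K = d.G, d.T, d.K

        off1 = np.atleast_1d(np.asarray(nat["beta1_mean"]))[d.c_idx].astype(float)
        off2 = np.atleast_1d(np.asarray(nat["beta2_mean"]))[d.c_idx].astype(float)
        if K:
            g1 = np.asarray(nat["gamma1"]).reshape(G, K)
            off1 = off1 + np.einsum("rk,rk->r", d.X, g1[d.c_idx])
            if c.covariates_on_predictor2:
                g2 = np.asarray(nat["gamma2"]).reshape(G, K)
                off2 = off2 + np.einsum("rk,rk->r", d.X, g2[d.c_idx])
        if self.cens:
            ce1 = np.asarray(nat["census1"]).reshape(d.n_census - 1, G)
            ce2 = np.asarray(nat["census2"]).reshape(d.n_census - 1, G)
            nonref = d.cens_idx > 0
            off1[nonref] += ce1[d.cens_idx[nonref] - 1, d.c_idx[nonref]]
            off2[nonref] += ce2[d.cens_idx[nonref] - 1, d.c_idx[nonref]]

        A1 = self._jacobian(self._cols1, self._base_wts1, self._kinds1, nat)
        A2 = self._jacobian(self._cols2, self._base_wts2, self._kinds2, nat)

        P = np.zeros((self.n_u, self.n_u))
        logdet_sigma = 0.0
        if self.Fsp or self.Fst:
            C = matern_correlation(self.anchor_dists, float(nat["range_km"]))
            C += c.jitter * np.eye(self.M)
            cf, _ = _chol_jitter(C, c.jitter, "Matern correlation")
            logdetR = 2.0 * np.sum(np.log(np.diag(cf[0])))
            Rinv = cho_solve(cf, np.eye(self.M))
            if self.Fsp:
                blk = np.kron(Rinv, np.eye(self.Fsp))
                P[self.blocks["psi1"], self.blocks["psi1"]] = blk
                logdet_sigma += self.Fsp * logdetR
                if self.use2:
                    P[self.blocks["psi2"], self.blocks["psi2"]] = blk
                    logdet_sigma += self.Fsp * logdetR
            if self.Fst:
                blk = np.kron(Rinv, np.eye(T * self.Fst))
                P[self.blocks["phi1"], self.blocks["phi1"]] = blk
                logdet_sigma += T * self.Fst * logdetR
                if self.use2:
                    P[self.blocks["phi2"], self.blocks["phi2"]] = blk
                    logdet_sigma += T * self.Fst * logdetR

        rho = float(nat.get("ar1_rho", 0.0))
        sd1 = float(nat["ar1_sd"])
        Q = _ar1_precision(T, rho, sd1)
        P[self.blocks["db1"], self.blocks["db1"]] = np.kron(np.eye(G), Q)
        logdet_sigma += G * (T * np.log(sd1**2) - np.log1p(-(rho**2)))
        if self.iid2:
            sd2 = float(nat["beta2_sd"])
            sl = self.blocks["db2"]
            P[sl, sl] = np.eye(G * T) / sd2**2
            logdet_sigma += G * T * np.log(sd2**2)
        if self.od:
            for name, key in (("eta1", "od_sd1"), ("eta2", "od_sd2")):
                sdo = float(nat[key])
                sl = self.blocks[name]
                n = sl.stop - sl.start
                P[sl, sl] = np.eye(n) / sdo**2
                logdet_sigma += n * np.log(sdo**2)

        prior_const = 0.5 * (logdet_sigma + self.n_u * _LOG2PI)
        kshape = 1.0 / np.atleast_1d(np.asarray(nat["sigma_m"]))[d.c_idx] ** 2
        return {
            "nat": nat, "off1": off1, "off2": off2, "A1": A1, "A2": A2,
            "P": P, "prior_const": prior_const, "k": kshape,
        }

    # -- joint likelihood ---------------------------------------------------

    def predictors(self, prep, u):
        p1 = prep["off1"] + prep["A1"] @ u
        p2 = prep["off2"] + prep["A2"] @ u
        return p1, p2

    def joint_fg(self, prep, u, want_grad=True):
        d = self.data
        p1, p2 = self.predictors(prep, u)
        ll, g1, g2, *_ = _obs_loglik_derivs(
            d.B, p1, p2, d.loga, prep["k"], want_derivs=want_grad
        )
        Pu = prep["P"] @ u
        f = -np.sum(ll) + 0.5 * (u @ Pu) + prep["prior_const"]
        if not np.isfinite(f):
            raise NumericalError("non-finite joint NLL")
        if not want_grad:
            return f, None
        g = -(prep["A1"].T @ g1) - (prep["A2"].T @ g2) + Pu
        return f, g

    def joint_hess(self, prep, u):
        d = self.data
        p1, p2 = self.predictors(prep, u)
        _, _, _, h11, h12, h22 = _obs_loglik_derivs(d.B, p1, p2, d.loga, prep["k"])
        A1, A2 = prep["A1"], prep["A2"]
        W11 = sp.diags(-h11)
        W22 = sp.diags(-h22)
        W12 = sp.diags(-h12)
        H = (A1.T @ W11 @ A1 + A2.T @ W22 @ A2).toarray()
        Hx = (A1.T @ W12 @ A2).toarray()
        H += Hx + Hx.T
        H += prep["P"]
        return H

    def inner_mode(self, prep, u0=None):
        """Damped Newton to the random-effect mode of the joint NLL."""
        c = self.config
        u = np.zeros(self.n_u) if u0 is None else u0.copy()
        f, g = self.joint_fg(prep, u)
        for _ in range(c.max_inner_iter):
            if np.max(np.abs(g)) < c.inner_gtol:
                break
            H = self.joint_hess(prep, u)
            cf, _ = _chol_jitter(H, max(c.jitter, 1e-10), "inner Hessian")
            step = cho_solve(cf, g)
            t, ok = 1.0, False
            gs = g @ step
            while t > 1e-10:
                try:
                    fn, gn = self.joint_fg(prep, u - t * step)
                except NumericalError:
                    t *= 0.5
                    continue
                if fn <= f - 1e-4 * t * gs + 1e-12:
                    u, f, g = u - t * step, fn, gn
                    ok = True
                    break
                t *= 0.5
            if not ok:
                break
        else:
            raise ConvergenceError(
                f"inner Newton did not reach tolerance "
                f"(grad max {np.max(np.abs(g)):.2e})"
            )
        H = self.joint_hess(prep, u)
        return u, f, H

    def laplace(self, nat: dict, u0=None):
        """Laplace-approximated marginal NLL and the random-effect mode."""
        prep = self.prepare(nat)
        if self.n_u == 0:
            f, _ = self.joint_fg(prep, np.zeros(0), want_grad=False)
            return f, np.zeros(0)
        u, f, H = self.inner_mode(prep, u0)
        cf, _ = _chol_jitter(H, max(self.config.jitter, 1e-10), "Laplace Hessian")
        logdetH = 2.0 * np.sum(np.log(np.diag(cf[0])))
        val = f + 0.5 * logdetH - 0.5 * self.n_u * _LOG2PI
        return val, u

    def objective(self, z: np.ndarray) -> float:
        """Outer objective over the transformed fixed-effect vector."""
        self.n_evaluations += 1
        try:
            nat = self.spec.unpack(z)
            val, u = self.laplace(nat, self._u_cache)
        except (NumericalError, ValidationError):
            return 1e10
        if not np.isfinite(val):
            return 1e10
        self._u_cache = u
        return float(val)

    # -- initialization -----------------------------------------------------

    def initial_natural(self) -> dict:
        d = self.data
        rng = np.random.default_rng(self.config.seed)
        nat = {}
        pos = d.B > 0
        abar = float(np.mean(d.area))
        mu1 = np.zeros(d.G)
        mu2 = np.zeros(d.G)
        for c in range(d.G):
            sel = d.c_idx == c
            p_hat = float(np.clip(np.mean(pos[sel]), 0.02, 0.98))
            n_hat = -np.log1p(-p_hat) / abar
            mu1[c] = np.log(n_hat)
            mpos = float(np.mean(d.B[sel & pos])) if np.any(sel & pos) else 1.0
            w_hat = max(mpos * p_hat / (abar * n_hat), 1e-6)
            mu2[c] = np.log(w_hat)
        nat["beta1_mean"] = mu1
        nat["beta2_mean"] = mu2
        if self.config.estimate_ar1:
            nat["ar1_rho"] = 0.3
        nat["ar1_sd"] = 0.5
        if self.iid2:
            nat["beta2_sd"] = 0.3
        if d.K:
            nat["gamma1"] = np.zeros(d.G * d.K)
            if self.config.covariates_on_predictor2:
                nat["gamma2"] = np.zeros(d.G * d.K)
        for name, F in (
            ("L_omega1", self.Fsp), ("L_omega2", self.Fsp if self.use2 else 0),
            ("L_eps1", self.Fst), ("L_eps2", self.Fst if self.use2 else 0),
        ):
            if F and (name, len(_tril_indices(d.G, F)), "id") in [
                (e[0], e[1], e[2]) for e in self.spec.entries
            ]:
                vec = np.array(
                    [0.3 if c == f else 0.05 for (c, f) in _tril_indices(d.G, F)]
                )
                nat[name] = vec
        if self.Fsp or self.Fst:
            extent = float(np.max(np.ptp(self.data.coords, axis=0)))
            nat["range_km"] = max(extent / 5.0, 1.0)
        nat["sigma_m"] = np.full(d.G, 0.8)
        if self.od:
            nat["od_sd1"] = 0.3
            nat["od_sd2"] = 0.3
        if self.cens:
            n = (d.n_census - 1) * d.G
            nat["census1"] = np.zeros(n)
            nat["census2"] = np.zeros(n)
        z = self.spec.pack(nat)
        z = z + 0.01 * rng.standard_normal(z.size)
        return self.spec.unpack(z)


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def linear_predictors(biomass_df, sites_df, design_df, config, params, random_effects):
    """Row-aligned (p1, p2) for explicit parameters and random effects.

    ``params`` is a dict of natural parameters; ``random_effects`` maps
    block names ("psi1", "phi1", "db1", ...) to arrays (flattened in the
    block's native layout).  Missing blocks default to zero.
    """
    data = FitData(biomass_df, sites_df, design_df)
    asm = _Assembler(data, config)
    u = np.zeros(asm.n_u)
    for name, arr in (random_effects or {}).items():
        if name not in asm.blocks:
            raise ValidationError(f"unknown random-effect block {name!r}")
        u[asm.blocks[name]] = np.asarray(arr, dtype=float).ravel()
    prep = asm.prepare(params)
    return asm.predictors(prep, u)


def joint_nll(biomass_df, sites_df, design_df, config, params, random_effects):
    """Joint negative log-likelihood of data and random effects."""
    data = FitData(biomass_df, sites_df, design_df)
    asm = _Assembler(data, config)
    u = np.zeros(asm.n_u)
    for name, arr in (random_effects or {}).items():
        if name not in asm.blocks:
            raise ValidationError(f"unknown random-effect block {name!r}")
        u[asm.blocks[name]] = np.asarray(arr, dtype=float).ravel()
    prep = asm.prepare(params)
    f, _ = asm.joint_fg(prep, u, want_grad=False)
    return float(f)


def laplace_marginal_nll(biomass_df, sites_df, design_df, config, params):
    """Laplace-approximated marginal NLL and random-effect modes."""
    data = FitData(biomass_df, sites_df, design_df)
    asm = _Assembler(data, config)
    val, u = asm.laplace(params)
    modes = {name: np.array(u[sl]) for name, sl in asm.blocks.items()}
    return float(val), modes


@dataclass
class FitResult:
    """Maximum-marginal-likelihood fit of the model."""

    params: dict
    param_names: list[str]
    theta: np.ndarray  # natural-scale flat vector, aligned with param_names
    cov: Optional[np.ndarray]  # natural-scale fixed-effect covariance
    marginal_nll: float
    saturated_nll: float
    grad_norm: float
    converged: bool
    n_evaluations: int
    modes: dict
    config: ModelConfig
    data: FitData = field(repr=False)
    _assembler: _Assembler = field(repr=False, default=None)

    def index_of(self, name: str) -> int:
        return self.param_names.index(name)

    def estimate(self, name: str) -> float:
        return float(self.theta[self.index_of(name)])

    def se(self, name: str) -> float:
        if self.cov is None:
            raise ValidationError("fit was run without standard errors")
        i = self.index_of(name)
        return float(np.sqrt(max(self.cov[i, i], 0.0)))

    def gamma1_matrix(self) -> np.ndarray:
        G, K = self.data.G, self.data.K
        return np.asarray(self.params["gamma1"]).reshape(G, K)

    def to_json(self, path):
        payload = {
            "params": {k: np.asarray(v).tolist() for k, v in self.params.items()},
            "param_names": self.param_names,
            "theta": self.theta.tolist(),
            "se": (
                np.sqrt(np.clip(np.diag(self.cov), 0, None)).tolist()
                if self.cov is not None else None
            ),
            "marginal_nll": self.marginal_nll,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_evaluations": self.n_evaluations,
            "groups": self.data.groups.tolist(),
            "covariates": list(self.data.covariates),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _saturated_nll(data: FitData, sigma_m: np.ndarray) -> float:
    """NLL of the saturated model: occurrence matched exactly, Gamma mean = B."""
    k = 1.0 / np.atleast_1d(np.asarray(sigma_m))[data.c_idx] ** 2
    pos = data.B > 0
    ll = np.zeros(data.n_rows)
    kp, Bp = k[pos], data.B[pos]
    scale = Bp / kp
    ll[pos] = (
        -(kp) + (kp - 1) * np.log(Bp) - kp * np.log(scale) - gammaln(kp)
    )
    return float(-np.sum(ll))


def fit_jdsdm(
    biomass_df, sites_df, design_df=None, config: ModelConfig | None = None,
    start: dict | None = None,
) -> FitResult:
    """Fit the model by maximizing the Laplace marginal likelihood."""
    config = config or ModelConfig()
    data = FitData(biomass_df, sites_df, design_df)
    if data.T < 2:
        raise ValidationError("need at least 2 years")
    if data.S < 2:
        raise ValidationError("need at least 2 sites")
    asm = _Assembler(data, config)

    nat0 = start or asm.initial_natural()
    z0 = asm.spec.pack(nat0)
    res = minimize(
        asm.objective, z0, method="L-BFGS-B",
        options={
            "maxiter": config.max_outer_iter,
            "maxfun": 200000,
            "eps": config.fd_eps,
            "ftol": 1e-13,
            "gtol": config.outer_gtol / 10.0,
        },
    )
    z = res.x
    grad = approx_fprime(z, asm.objective, config.fd_eps)
    grad_norm = float(np.max(np.abs(grad)))
    converged = bool(np.isfinite(res.fun)) and grad_norm <= config.outer_gtol
    if not converged:
        warnings.warn(
            f"outer optimizer did not meet tolerance (grad max {grad_norm:.2e}, "
            f"message {res.message!r})",
            stacklevel=2,
        )

    nat = asm.spec.unpack(z)
    val, u = asm.laplace(nat, asm._u_cache)
    modes = {name: np.array(u[sl]) for name, sl in asm.blocks.items()}

    cov = None
    if config.compute_se:
        from statsmodels.tools.numdiff import approx_hess2

        Hz = approx_hess2(z, asm.objective, epsilon=config.hess_eps)
        Hz = 0.5 * (Hz + Hz.T)
        evals = np.linalg.eigvalsh(Hz)
        if evals.min() <= 0:
            # FD noise or a flat direction; retry with a coarser step
            Hz = approx_hess2(z, asm.objective, epsilon=10 * config.hess_eps)
            Hz = 0.5 * (Hz + Hz.T)
            evals = np.linalg.eigvalsh(Hz)
        if evals.min() <= 0:
            # repair by eigenvalue clipping: flat directions receive
            # large (conservative) variances rather than spurious zeros
            warnings.warn(
                "outer Hessian not positive definite; clipping "
                f"{int(np.sum(evals <= 0))} flat direction(s) — standard "
                "errors there are lower bounds on the uncertainty",
                stacklevel=2,
            )
            w, V = np.linalg.eigh(Hz)
            floor = max(evals.max(), 1.0) * 1e-8
            w = np.maximum(w, floor)
            cov_z = (V / w) @ V.T
        else:
            cov_z = np.linalg.inv(Hz)
        J = asm.spec.natural_jacobian_diag(z)
        cov = cov_z * np.outer(J, J)

    theta = np.concatenate(
        [np.atleast_1d(np.asarray(nat[e[0]], dtype=float)).ravel()
         for e in asm.spec.entries]
    )
    names = _flat_natural_names(asm)
    return FitResult(
        params=nat,
        param_names=names,
        theta=theta,
        cov=cov,
        marginal_nll=float(val),
        saturated_nll=_saturated_nll(data, nat["sigma_m"]),
        grad_norm=grad_norm,
        converged=converged,
        n_evaluations=asm.n_evaluations,
        modes=modes,
        config=config,
        data=data,
        _assembler=asm,
    )


def _flat_natural_names(asm: _Assembler) -> list[str]:
    """Descriptive flat names, expanding matrix-valued blocks."""
    d = asm.data
    names = []
    for name, n, _tf in asm.spec.entries:
        if name in ("gamma1", "gamma2") and d.K:
            for c in range(d.G):
                for k in range(d.K):
                    names.append(f"{name}[{d.groups[c]},{d.covariates[k]}]")
        elif name.startswith("L_"):
            F = asm.Fsp if "omega" in name else asm.Fst
            for (c, f) in _tril_indices(d.G, F):
                names.append(f"{name}[{c},{f}]")
        elif name in ("beta1_mean", "beta2_mean", "sigma_m"):
            names.extend(f"{name}[{d.groups[c]}]" for c in range(d.G))
        elif name in ("census1", "census2"):
            for ct in d.census_types[1:]:
                for c in range(d.G):
                    names.append(f"{name}[{ct},{d.groups[c]}]")
        elif n == 1:
            names.append(name)
        else:
            names.extend(f"{name}[{i}]" for i in range(n))
    return names


def predict_density(fit: FitResult, sites=None, years=None,
                    allow_extrapolation=False) -> pd.DataFrame:
    """Per site x group x year predictions: n, w, r1, r2 and d = n * w."""
    if not fit.converged:
        warnings.warn("predicting from a non-converged fit", stacklevel=2)
    asm, d = fit._assembler, fit.data
    if years is not None:
        extra = set(years) - set(d.years.tolist())
        if extra and not allow_extrapolation:
            raise ValidationError(
                f"years {sorted(extra)} outside the fitted range; pass "
                "allow_extrapolation=True to use the stationary mean"
            )
    prep = asm.prepare(fit.params)
    u = np.concatenate([fit.modes[name] for name in asm.blocks]) if asm.n_u else np.zeros(0)
    p1, p2 = asm.predictors(prep, u)
    n = np.exp(np.clip(p1, -_PRED_CLIP, _PRED_CLIP))
    w = np.exp(np.clip(p2, -_PRED_CLIP, _PRED_CLIP))
    r1, r2 = poisson_link(n, w, d.area)
    out = d.rows[["site_id", "year", "group_id"]].copy()
    out["n"] = n
    out["w"] = w
    out["r1"] = r1
    out["r2"] = r2
    out["d"] = n * w
    out["area_offset"] = d.area
    if sites is not None:
        out = out[out["site_id"].isin(set(sites))]
    if years is not None:
        out = out[out["year"].isin(set(years))]
    return out.reset_index(drop=True)


def deviance_explained(fit, null_fit) -> float:
    """Proportion of delta-Gamma deviance explained relative to a null fit.

    deviance = 2 (marginal NLL - saturated NLL); returns
    1 - dev(full) / dev(null).  A negative value (null better than full)
    is returned with a warning rather than raised.
    """
    dev_full = 2.0 * (fit.marginal_nll - fit.saturated_nll)
    dev_null = 2.0 * (null_fit.marginal_nll - null_fit.saturated_nll)
    if dev_null <= 0:
        raise ValidationError("null deviance must be positive")
    out = 1.0 - dev_full / dev_null
    if out < 0:
        warnings.warn("null model fits better than full model", stacklevel=2)
    return float(out)


def quantile_residuals(fit: FitResult, seed: int = 0) -> np.ndarray:
    """Randomized-quantile residuals; standard-uniform under the true model.

    The cumulative probability at each observation is randomized within
    the zero atom: for B = 0, U ~ Uniform(0, 1 - r1); for B > 0,
    (1 - r1) + r1 * F_Gamma(B).
    """
    d = fit.data
    pred = predict_density(fit)
    r1 = pred["r1"].to_numpy()
    r2 = pred["r2"].to_numpy()
    k = 1.0 / np.atleast_1d(np.asarray(fit.params["sigma_m"]))[d.c_idx] ** 2
    rng = np.random.default_rng(seed)
    u = np.empty(d.n_rows)
    zero = d.B == 0
    u[zero] = rng.uniform(0.0, 1.0, zero.sum()) * (1.0 - r1[zero])
    pos = ~zero
    cdf = gammainc(k[pos], d.B[pos] * k[pos] / r2[pos])
    u[pos] = (1.0 - r1[pos]) + r1[pos] * cdf
    return np.clip(u, 0.0, 1.0)


def sample_delta_gamma(r1, r2, sigma_m, rng) -> np.ndarray:
    """Draw biomass from the Poisson-link delta-Gamma observation model."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    occ = rng.uniform(size=r1.shape) < r1
    k = 1.0 / np.asarray(sigma_m, dtype=float) ** 2
    k = np.broadcast_to(k, r1.shape)
    out = np.zeros(r1.shape)
    if occ.any():
        out[occ] = gamma_dist.rvs(
            a=k[occ], scale=r2[occ] / k[occ], random_state=rng
        )
    return out
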