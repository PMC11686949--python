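"""Post-fit effect assessment.

Delta-method standard errors from the outer-Hessian covariance,
Wald confidence intervals at a multiplicity-adjusted level (Bonferroni
over predictors x functional groups, e.g. 100 x (1 - 0.05 / (2 x 11))% =
99.8%), the empirical effect-size exceedance probability procedure, and
the time-lag sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import approx_fprime
from scipy.stats import binom, norm

from .covariates import lag_and_standardize
from .errors import ValidationError
from .model import ModelConfig, fit_jdsdm

__all__ = [
    "delta_method_se", "adjusted_ci_level", "flag_significant",
    "effects_table", "effect_exceedance_probability", "ExceedanceResult",
    "run_lag_sensitivity", "forest_plot",
]


def delta_method_se(fit, targets):
    """Standard errors of parameters or smooth functions of them.

    ``targets`` may be a parameter name, a list of names (diagonal SEs),
    a coefficient vector ``c`` (SE of c'theta), or a callable f(theta)
    whose gradient is obtained by finite differences.
    """
    if fit.cov is None:
        raise ValidationError("fit carries no fixed-effect covariance")
    cov = np.asarray(fit.cov)
    diag = np.diag(cov)
    if np.any(diag < -1e-8):
        bad = [fit.param_names[i] for i in np.nonzero(diag < -1e-8)[0]]
        raise ValidationError(f"covariance not PSD; non-identified: {bad[:5]}")

    if isinstance(targets, str):
        targets = [targets]
    if callable(targets):
        g = approx_fprime(fit.theta, targets, 1e-6)
        return float(np.sqrt(max(g @ cov @ g, 0.0)))
    if all(isinstance(t, str) for t in targets):
        idx = [fit.index_of(t) for t in targets]
        return np.sqrt(np.clip(diag[idx], 0.0, None))
    c = np.asarray(targets, dtype=float)
    if c.shape != (len(fit.theta),):
        raise ValidationError("coefficient vector length mismatch")
    return float(np.sqrt(max(c @ cov @ c, 0.0)))


def adjusted_ci_level(base_alpha: float, n_predictors: int, n_groups: int) -> float:
    """Bonferroni-adjusted confidence level 1 - alpha / (n_pred * n_groups)."""
    if not 0 < base_alpha < 1:
        raise ValidationError("base_alpha must lie in (0, 1)")
    if n_predictors < 1 or n_groups < 1:
        raise ValidationError("counts must be >= 1")
    return 1.0 - base_alpha / (n_predictors * n_groups)


def per_test_alpha(base_alpha: float, n_predictors: int, n_groups: int) -> float:
    """Implied single-test alpha of the adjusted level."""
    return 1.0 - adjusted_ci_level(base_alpha, n_predictors, n_groups)


@dataclass
class EffectEstimate:
    """One covariate effect with its adjusted Wald interval."""

    bird_group: str
    covariate: str
    predictor: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    significant: bool


def flag_significant(estimates, ses, level: float) -> pd.DataFrame:
    """Wald intervals estimate +/- z(level) * SE; significant iff 0 outside.

    Accepts aligned arrays; returns a frame with ci_low/ci_high and the
    significance flag.  Raising the level can only retract significance.
    """
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    z = norm.ppf(0.5 + level / 2.0)
    lo, hi = est - z * se, est + z * se
    return pd.DataFrame({
        "estimate": est, "se": se, "ci_low": lo, "ci_high": hi,
        "significant": (lo > 0) | (hi < 0),
    })


def effects_table(
    fit, level: float | None = None, base_alpha: float = 0.05,
    predictors=(1, 2), region: str | None = None,
) -> pd.DataFrame:
    """Covariate-effect estimates for each predictor x group x covariate.

    The confidence level defaults to the Bonferroni adjustment over
    (number of predictors reported) x (number of groups).
    """
    d = fit.data
    if d.K == 0:
        raise ValidationError("fit has no covariates")
    preds = [p for p in predictors if p == 1 or "gamma2" in fit.params]
    if level is None:
        level = adjusted_ci_level(base_alpha, len(preds), d.G)
    rows = []
    for p in preds:
        stem = f"gamma{p}"
        for c in range(d.G):
            for k in range(d.K):
                name = f"{stem}[{d.groups[c]},{d.covariates[k]}]"
                est = fit.estimate(name)
                se = fit.se(name)
                rows.append({
                    "region": region, "bird_group": d.groups[c],
                    "covariate": d.covariates[k], "predictor": p,
                    "estimate": est, "se": se,
                })
    out = pd.DataFrame(rows)
    wald = flag_significant(out["estimate"], out["se"], level)
    out[["ci_low", "ci_high", "significant"]] = wald[
        ["ci_low", "ci_high", "significant"]
    ]
    out["level"] = level
    return out


@dataclass
class ExceedanceResult:
    """Probability of observing >= k effects at least as large as a threshold."""

    threshold: float
    k: int
    family_size: int
    p_tail: float
    probability: float
    method: str

    def to_json(self, path):
        import json
        from dataclasses import asdict

        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def effect_exceedance_probability(
    all_effects,
    threshold: float,
    k: int,
    family_size: int,
    method: str = "binomial",
    n_resample: int = 100_000,
    seed: int = 0,
) -> ExceedanceResult:
    """Empirical-CDF probability of >= k effects with |size| >= threshold.

    The tail probability of a single effect is the fraction of the
    pooled |effect| distribution at or above the threshold; the chance
    of at least ``k`` such effects within a family of ``family_size``
    comparisons is a binomial tail (default) or a Monte-Carlo resample
    from the empirical distribution (the two agree within MC error).
    """
    eff = np.abs(np.asarray(all_effects, dtype=float))
    if eff.size < 2:
        raise ValidationError("need at least 2 effect sizes")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if family_size < k:
        raise ValidationError("family size must be >= k")
    p_tail = float(np.mean(eff >= threshold))
    if p_tail == 0.0:
        warnings.warn("threshold exceeds all effects; probability 0", stacklevel=2)
        return ExceedanceResult(threshold, k, family_size, 0.0, 0.0, method)
    if method == "binomial":
        prob = float(binom.sf(k - 1, family_size, p_tail))
    elif method == "resample":
        rng = np.random.default_rng(seed)
        draws = rng.choice(eff, size=(n_resample, family_size), replace=True)
        prob = float(np.mean(np.sum(draws >= threshold, axis=1) >= k))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return ExceedanceResult(threshold, k, family_size, p_tail, prob, method)


def run_lag_sensitivity(
    biomass_df, sites_df, anomalies_df, lags, config: ModelConfig,
    analysis_years=None,
) -> pd.DataFrame:
    """Refit the model per candidate lag; flag the best by marginal AIC.

    ``anomalies_df`` holds the unlagged anomaly series (site_id,
    covariate, year, value); for each lag the design is realigned and
    standardized, the model refitted, and marginal NLL / AIC reported.
    Non-converging lags are reported as failed, never dropped.
    """
    lags = list(lags)
    if not lags:
        raise ValidationError("need at least one candidate lag")
    if analysis_years is None:
        analysis_years = sorted(biomass_df["year"].unique())
    rows = []
    for lag in lags:
        try:
            design = lag_and_standardize(anomalies_df, lag, analysis_years)
            fit = fit_jdsdm(biomass_df, sites_df, design, config)
            n_fixed = len(fit.theta)
            rows.append({
                "lag": lag, "converged": fit.converged,
                "marginal_nll": fit.marginal_nll,
                "aic": 2.0 * fit.marginal_nll + 2.0 * n_fixed,
                "n_fixed_effects": n_fixed,
                "mean_gamma1": float(np.mean(fit.gamma1_matrix())),
                "error": None,
            })
        except Exception as exc:  # failed lag is reported, not dropped
            rows.append({
                "lag": lag, "converged": False, "marginal_nll": np.nan,
                "aic": np.nan, "n_fixed_effects": np.nan,
                "mean_gamma1": np.nan, "error": str(exc),
            })
    out = pd.DataFrame(rows)
    finite = out["aic"].notna()
    out["best"] = False
    if finite.any():
        out.loc[out.loc[finite, "aic"].idxmin(), "best"] = True
    return out


def forest_plot(effects: pd.DataFrame, path=None, ax=None):
    """Minimal forest plot of an effects table (estimate + interval)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(6, 0.4 * len(effects) + 1.5), constrained_layout=True
        )
    labels = [
        f"{r.bird_group} ~ {r.covariate}" for r in effects.itertuples()
    ]
    y = np.arange(len(effects))
    ax.hlines(y, effects["ci_low"], effects["ci_high"], color="0.4")
    filled = effects["significant"].to_numpy(bool)
    ax.scatter(effects["estimate"][~filled], y[~filled], facecolors="white",
               edgecolors="k", zorder=3)
    ax.scatter(effects["estimate"][filled], y[filled], color="k", zorder=3)
    ax.axvline(0.0, color="0.7", lw=0.8)
    ax.set_yticks(y, labels)
    ax.set_xlabel("effect size (standardized covariate)")
    if path is not None:
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
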