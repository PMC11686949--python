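"""Lagged, standardized covariate construction.

Per-trap annual moth-group biomass series become ln-anomalies (deviation
of ln biomass from that trap's long-term mean), which are spatially
interpolated to the bird observation sites; breeding-season climate
series become anomalies relative to a reference period.  Anomalies are
then shifted by the analysis lag (default one year: prey abundance in
year t-1 drives predator abundance in year t) and standardized to zero
mean / unit variance over the analysed rows.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .errors import AlignmentError, ValidationError

logger = logging.getLogger(__name__)

#: Amount (mg) added to biomass before the log so zero catches stay finite.
DEFAULT_EPSILON = 1.0


def compute_ln_anomaly(
    series: pd.DataFrame,
    epsilon: float = DEFAULT_EPSILON,
    value_col: str = "biomass",
) -> pd.DataFrame:
    """Per-trap ln-anomalies of an annual biomass series.

    value(s, t) = ln(biomass + eps) - mean_t' ln(biomass(s, t') + eps),
    the mean running over that trap's observed years, so trap-effort
    differences cancel.  Traps with a single observed year carry no
    anomaly information and are dropped with a warning.

    ``series`` needs ``site_id``, ``year`` and ``value_col`` columns; an
    optional ``covariate`` column is preserved and anomalies are computed
    within each (site, covariate) pair.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    if (series[value_col] < 0).any():
        raise ValidationError("biomass must be non-negative")
    keys = ["site_id"] + (["covariate"] if "covariate" in series.columns else [])

    n_years = series.groupby(keys)["year"].transform("nunique")
    single = n_years < 2
    if single.any():
        dropped = series.loc[single, "site_id"].unique()
        logger.warning(
            "excluding %d trap series with a single observed year: %s",
            len(dropped), list(dropped)[:10],
        )
        series = series[~single]
    out = series.copy()
    ln = np.log(out[value_col].to_numpy(float) + epsilon)
    out["value"] = ln - pd.Series(ln, index=out.index).groupby(
        [out[k] for k in keys]
    ).transform("mean")
    cols = keys[:1] + (["covariate"] if "covariate" in out.columns else [])
    return out[cols + ["year", "value"]].reset_index(drop=True)


def _idw_weights(dists: np.ndarray, power: float, delta: float) -> np.ndarray:
    """Inverse-distance weights for one target; exact hit takes all weight."""
    hits = dists <= 1e-9
    if hits.any():
        w = hits.astype(float)
    else:
        w = (dists + delta) ** (-power)
    return w / w.sum()


def interpolate_to_sites(
    anomalies: pd.DataFrame,
    trap_coords: pd.DataFrame,
    target_sites: pd.DataFrame,
    method: str = "idw",
    power: float = 2.0,
    delta: float = 0.0,
    bandwidth_km: float = 50.0,
) -> pd.DataFrame:
    """Interpolate trap anomalies to target sites, per year (and covariate).

    method "idw": weights (distance + delta)^-power, normalized; a target
    coinciding with a trap receives that trap's value exactly.
    method "gaussian_kernel": weights exp(-d^2 / (2 bandwidth^2)).
    Years with no trap value are skipped (missing value propagated).
    """
    if method not in ("idw", "gaussian_kernel"):
        raise ValidationError(f"unknown interpolation method {method!r}")
    for df, name in ((trap_coords, "trap_coords"), (target_sites, "target_sites")):
        if not {"site_id", "x", "y"} <= set(df.columns):
            raise ValidationError(f"{name} needs site_id, x, y columns")

    traps = trap_coords.drop_duplicates("site_id").set_index("site_id")
    targets = target_sites.drop_duplicates("site_id")
    txy = targets[["x", "y"]].to_numpy(float)

    has_cov = "covariate" in anomalies.columns
    group_keys = (["covariate"] if has_cov else []) + ["year"]
    rows = []
    for key, grp in anomalies.groupby(group_keys):
        key = key if isinstance(key, tuple) else (key,)
        trap_ids = grp["site_id"].to_numpy()
        known = [t for t in trap_ids if t in traps.index]
        if not known:
            logger.warning("no trap values for %s; missing propagated", key)
            continue
        grp = grp[grp["site_id"].isin(known)]
        sxy = traps.loc[grp["site_id"], ["x", "y"]].to_numpy(float)
        vals = grp["value"].to_numpy(float)
        D = cdist(txy, sxy)
        if method == "idw":
            W = np.vstack([_idw_weights(d, power, delta) for d in D])
        else:
            W = np.exp(-0.5 * (D / bandwidth_km) ** 2)
            # exact hits dominate numerically already; normalize rows
            W = W / W.sum(axis=1, keepdims=True)
        interp = W @ vals
        base = {"covariate": key[0]} if has_cov else {}
        year = key[-1]
        for sid, v in zip(targets["site_id"], interp):
            rows.append({**base, "site_id": sid, "year": year, "value": v})
    out = pd.DataFrame(rows)
    order = (["covariate"] if has_cov else []) + ["site_id", "year"]
    return out.sort_values(order, ignore_index=True) if len(out) else out


def paired_correlation(observed, interpolated) -> float:
    """Pearson correlation between observed and interpolated values."""
    x = np.asarray(observed, dtype=float)
    y = np.asarray(interpolated, dtype=float)
    if x.size < 3:
        raise ValidationError("need >= 3 paired values for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    return float(pearsonr(x, y)[0])


def validate_interpolation(
    anomalies: pd.DataFrame,
    trap_coords: pd.DataFrame,
    by: list[str] | None = None,
    method: str = "idw",
    **kwargs,
) -> pd.DataFrame:
    """Leave-one-trap-out interpolation accuracy as Pearson correlations.

    Each trap's anomaly is predicted from the remaining traps; the
    returned frame has one row per group in ``by`` (for example region x
    moth group) plus an "overall" row, with the correlation between
    observed and predicted values.
    """
    traps = trap_coords.drop_duplicates("site_id").reset_index(drop=True)
    preds = []
    for sid in traps["site_id"]:
        held = anomalies[anomalies["site_id"] == sid]
        if held.empty:
            continue
        rest = anomalies[anomalies["site_id"] != sid]
        target = traps[traps["site_id"] == sid]
        est = interpolate_to_sites(rest, traps, target, method=method, **kwargs)
        if est.empty:
            continue
        keys = ["site_id", "year"] + (
            ["covariate"] if "covariate" in anomalies.columns else []
        )
        merged = held.merge(est, on=keys, suffixes=("_obs", "_pred"))
        preds.append(merged)
    if not preds:
        raise ValidationError("no leave-one-out pairs could be formed")
    paired = pd.concat(preds, ignore_index=True)

    def _corr(df):
        return paired_correlation(
            df["value_obs"].to_numpy(float), df["value_pred"].to_numpy(float)
        )

    rows = [{"scope": "overall", "r": _corr(paired), "n": len(paired)}]
    if by:
        if "region" in by and "region" not in paired.columns and "region" in traps.columns:
            paired = paired.merge(traps[["site_id", "region"]], on="site_id")
        for key, grp in paired.groupby(by):
            key = key if isinstance(key, tuple) else (key,)
            rows.append(
                {"scope": "/".join(map(str, key)), "r": _corr(grp), "n": len(grp)}
            )
    return pd.DataFrame(rows)


def compute_climate_anomaly(
    climate: pd.DataFrame,
    reference_years: tuple[int, int],
    value_cols: tuple[str, ...] = ("temperature", "precipitation"),
) -> pd.DataFrame:
    """Per-site anomalies relative to the mean over a reference period.

    Returns long-format rows (site_id, covariate, year, value).  Sites
    with no observation inside the reference period are excluded with a
    warning.
    """
    lo, hi = reference_years
    in_ref = climate["year"].between(lo, hi)
    ref_sites = set(climate.loc[in_ref, "site_id"])
    missing = sorted(set(climate["site_id"]) - ref_sites)
    if missing:
        logger.warning(
            "excluding %d site(s) with no reference-period climate: %s",
            len(missing), missing[:10],
        )
        climate = climate[climate["site_id"].isin(ref_sites)]
    frames = []
    for col in value_cols:
        ref_mean = (
            climate[climate["year"].between(lo, hi)]
            .groupby("site_id")[col]
            .mean()
        )
        sub = climate[["site_id", "year", col]].copy()
        sub["value"] = sub[col] - sub["site_id"].map(ref_mean)
        sub["covariate"] = col
        frames.append(sub[["site_id", "covariate", "year", "value"]])
    return pd.concat(frames, ignore_index=True)


def lag_and_standardize(
    anomalies: pd.DataFrame,
    lag: int,
    analysis_years: list[int],
    standardize: bool = True,
) -> pd.DataFrame:
    """Shift anomalies forward by ``lag`` years and standardize columns.

    The covariate value attached to (site, t) is the anomaly observed at
    (site, t - lag).  Every analysed site/year must have a source value;
    a missing one raises an alignment error naming the site and year.
    Each covariate column is then centred and scaled over the analysed
    rows (mean 0, sd 1).
    """
    if lag < 0:
        raise ValidationError("lag must be non-negative")
    if not {"site_id", "covariate", "year", "value"} <= set(anomalies.columns):
        raise ValidationError(
            "anomalies need site_id, covariate, year, value columns"
        )
    shifted = anomalies.copy()
    shifted["year"] = shifted["year"] + lag
    design = shifted[shifted["year"].isin(analysis_years)].copy()

    sites = anomalies["site_id"].unique()
    covs = anomalies["covariate"].unique()
    expected = len(sites) * len(covs) * len(analysis_years)
    if len(design) < expected:
        have = set(zip(design["site_id"], design["covariate"], design["year"]))
        for s in sites:
            for c in covs:
                for t in analysis_years:
                    if (s, c, t) not in have:
                        raise AlignmentError(
                            f"no lag-{lag} source value for site {s!r}, "
                            f"covariate {c!r}, year {t} (needs year {t - lag})"
                        )
    design["lag_applied"] = lag
    if standardize:
        grp = design.groupby("covariate")["value"]
        mean, sd = grp.transform("mean"), grp.transform("std", ddof=0)
        if (sd == 0).any():
            flat = design.loc[sd == 0, "covariate"].unique()
            raise ValidationError(f"constant covariate column(s): {sorted(flat)}")
        design["value"] = (design["value"] - mean) / sd
    return design.sort_values(
        ["covariate", "site_id", "year"], ignore_index=True
    )[["site_id", "covariate", "year", "value", "lag_applied"]]
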