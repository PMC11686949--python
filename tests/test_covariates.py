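"""Anomaly construction, interpolation, lagging and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trophdyn.covariates import (
    compute_climate_anomaly,
    compute_ln_anomaly,
    interpolate_to_sites,
    lag_and_standardize,
    paired_correlation,
    validate_interpolation,
)
from trophdyn.errors import AlignmentError, ValidationError
from trophdyn.model import matern_correlation


def _series(values, site="t1", years=None):
    years = years or list(range(2000, 2000 + len(values)))
    return pd.DataFrame({"site_id": site, "year": years, "biomass": values})


class TestLnAnomaly:
    def test_constant_series_is_zero(self):
        out = compute_ln_anomaly(_series([10.0] * 5), epsilon=1.0)
        assert np.allclose(out["value"], 0.0)

    def test_forced_values(self):
        eps = 0.5
        series = _series([np.e - eps, np.e**3 - eps])
        out = compute_ln_anomaly(series, epsilon=eps)
        assert np.allclose(sorted(out["value"]), [-1.0, 1.0], atol=1e-12)

    @given(st.lists(st.floats(0.0, 1e5), min_size=2, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_per_trap_mean_zero(self, values):
        out = compute_ln_anomaly(_series(values))
        assert abs(out["value"].mean()) < 1e-10

    def test_single_year_trap_excluded(self):
        df = pd.concat([_series([1.0, 2.0]), _series([3.0], site="solo")])
        out = compute_ln_anomaly(df)
        assert "solo" not in set(out["site_id"])


def _coords(ids_xy):
    return pd.DataFrame(
        [{"site_id": s, "x": x, "y": y} for s, (x, y) in ids_xy.items()]
    )


class TestInterpolation:
    def test_single_trap_dominates(self):
        anoms = pd.DataFrame({"site_id": ["t1"], "year": [2000], "value": [0.7]})
        traps = _coords({"t1": (0, 0)})
        targets = _coords({"b1": (10, 5), "b2": (90, 90)})
        out = interpolate_to_sites(anoms, traps, targets)
        assert np.allclose(out["value"], 0.7)

    def test_equidistant_symmetry(self):
        anoms = pd.DataFrame({
            "site_id": ["t1", "t2"], "year": 2000, "value": [-1.0, 1.0]
        })
        traps = _coords({"t1": (0, 0), "t2": (10, 0)})
        targets = _coords({"mid": (5, 0)})
        out = interpolate_to_sites(anoms, traps, targets)
        assert out["value"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_exact_hit_returns_trap_value(self):
        anoms = pd.DataFrame({
            "site_id": ["t1", "t2"], "year": 2000, "value": [-1.0, 1.0]
        })
        traps = _coords({"t1": (0, 0), "t2": (10, 0)})
        targets = _coords({"hit": (0, 0)})
        out = interpolate_to_sites(anoms, traps, targets)
        assert out["value"].iloc[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize("method", ["idw", "gaussian_kernel"])
    def test_values_within_trap_range(self, method):
        rng = np.random.default_rng(0)
        traps = _coords({f"t{i}": tuple(rng.uniform(0, 100, 2)) for i in range(8)})
        targets = _coords({f"b{i}": tuple(rng.uniform(0, 100, 2)) for i in range(20)})
        anoms = pd.DataFrame({
            "site_id": traps["site_id"], "year": 2000,
            "value": rng.normal(0, 1, len(traps)),
        })
        out = interpolate_to_sites(anoms, traps, targets, method=method)
        assert out["value"].min() >= anoms["value"].min() - 1e-12
        assert out["value"].max() <= anoms["value"].max() + 1e-12

    def test_smooth_field_recovered(self):
        # dense trap grid sampling a smooth Matern surface: interpolated
        # values at independent targets track the true surface closely
        rng = np.random.default_rng(5)
        gx, gy = np.meshgrid(np.linspace(0, 100, 8), np.linspace(0, 100, 8))
        trap_xy = np.column_stack([gx.ravel(), gy.ravel()])
        targ_xy = rng.uniform(5, 95, size=(40, 2))
        allxy = np.vstack([trap_xy, targ_xy])
        from scipy.spatial.distance import pdist, squareform

        C = matern_correlation(squareform(pdist(allxy)), 40.0)
        field = np.linalg.cholesky(C + 1e-8 * np.eye(len(C))) @ rng.standard_normal(len(C))
        traps = _coords({f"t{i}": tuple(xy) for i, xy in enumerate(trap_xy)})
        targets = _coords({f"b{i}": tuple(xy) for i, xy in enumerate(targ_xy)})
        anoms = pd.DataFrame({
            "site_id": traps["site_id"], "year": 2000, "value": field[: len(trap_xy)],
        })
        out = interpolate_to_sites(anoms, traps, targets).set_index("site_id")
        truth = pd.Series(field[len(trap_xy):], index=targets["site_id"])
        r = np.corrcoef(truth, out.loc[truth.index, "value"])[0, 1]
        assert r > 0.9


class TestPairedCorrelation:
    def test_perfect_and_anticorrelated(self):
        x = np.array([0.1, 0.5, -0.3, 0.9])
        assert paired_correlation(x, x) == pytest.approx(1.0)
        assert paired_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(9)
        assert abs(paired_correlation(
            rng.normal(size=1000), rng.normal(size=1000)
        )) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            paired_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_leave_one_out_on_smooth_field(self):
        rng = np.random.default_rng(2)
        gx, gy = np.meshgrid(np.linspace(0, 100, 5), np.linspace(0, 100, 5))
        xy = np.column_stack([gx.ravel(), gy.ravel()])
        from scipy.spatial.distance import pdist, squareform

        C = matern_correlation(squareform(pdist(xy)), 50.0)
        traps = _coords({f"t{i}": tuple(p) for i, p in enumerate(xy)})
        frames = []
        for year in (2000, 2001, 2002):
            f = np.linalg.cholesky(C + 1e-8 * np.eye(len(C))) @ rng.standard_normal(len(C))
            frames.append(pd.DataFrame({
                "site_id": traps["site_id"], "year": year, "value": f,
            }))
        res = validate_interpolation(pd.concat(frames), traps)
        overall = res.loc[res["scope"] == "overall", "r"].iloc[0]
        assert overall > 0.66  # the accuracy regime the design targets


class TestClimateAnomaly:
    def test_constant_climate_zero(self):
        clim = pd.DataFrame({
            "site_id": "a", "year": range(2000, 2005),
            "temperature": 10.0, "precipitation": 100.0,
        })
        out = compute_climate_anomaly(clim, (2000, 2004))
        assert np.allclose(out["value"], 0.0)

    def test_two_year_values(self):
        clim = pd.DataFrame({
            "site_id": "a", "year": [2000, 2001],
            "temperature": [10.0, 14.0], "precipitation": [0.0, 0.0],
        })
        out = compute_climate_anomaly(clim, (2000, 2001))
        temp = out[out["covariate"] == "temperature"].sort_values("year")
        assert np.allclose(temp["value"], [-2.0, 2.0])

    def test_reference_mean_identity(self):
        rng = np.random.default_rng(1)
        clim = pd.DataFrame({
            "site_id": np.repeat(["a", "b"], 10),
            "year": np.tile(range(2000, 2010), 2),
            "temperature": rng.normal(10, 2, 20),
            "precipitation": rng.normal(100, 20, 20),
        })
        out = compute_climate_anomaly(clim, (2000, 2009))
        means = out.groupby(["site_id", "covariate"])["value"].mean()
        assert np.all(np.abs(means) < 1e-10)


def _anoms(sites=("a", "b"), covs=("c1",), years=range(1999, 2005), seed=0):
    rng = np.random.default_rng(seed)
    rows = [
        {"site_id": s, "covariate": c, "year": y, "value": rng.normal()}
        for s in sites for c in covs for y in years
    ]
    return pd.DataFrame(rows)


class TestLagAndStandardize:
    def test_lag_zero_identity_alignment(self):
        anoms = _anoms()
        out = lag_and_standardize(anoms, 0, [2000, 2001], standardize=False)
        merged = out.merge(
            anoms, on=["site_id", "covariate", "year"], suffixes=("_d", "_a")
        )
        assert np.allclose(merged["value_d"], merged["value_a"])

    def test_lag_one_uses_previous_year(self):
        anoms = _anoms()
        out = lag_and_standardize(anoms, 1, [2000], standardize=False)
        src = anoms[anoms["year"] == 1999].set_index(["site_id", "covariate"])
        for row in out.itertuples():
            assert row.value == pytest.approx(
                src.loc[(row.site_id, row.covariate), "value"]
            )

    def test_columns_standardized(self):
        out = lag_and_standardize(_anoms(covs=("c1", "c2")), 1, [2000, 2001, 2002])
        grp = out.groupby("covariate")["value"]
        assert np.all(np.abs(grp.mean()) < 1e-8)
        assert np.allclose(grp.apply(lambda s: s.std(ddof=0)), 1.0, atol=1e-8)

    def test_shift_equivalence(self):
        anoms = _anoms()
        shifted = anoms.copy()
        shifted["year"] = shifted["year"] + 1
        a = lag_and_standardize(anoms, 1, [2001, 2002])
        b = lag_and_standardize(shifted, 0, [2001, 2002])
        merged = a.merge(
            b, on=["site_id", "covariate", "year"], suffixes=("_a", "_b")
        )
        assert np.allclose(merged["value_a"], merged["value_b"], atol=1e-12)

    def test_standardization_is_affine_bijection(self):
        anoms = _anoms()
        raw = lag_and_standardize(anoms, 1, [2000, 2001], standardize=False)
        std = lag_and_standardize(anoms, 1, [2000, 2001], standardize=True)
        m, s = raw["value"].mean(), raw["value"].std(ddof=0)
        back = std["value"] * s + m
        assert np.allclose(back, raw["value"], atol=1e-10)

    def test_missing_source_year_named(self):
        anoms = _anoms(years=range(2000, 2005))
        with pytest.raises(AlignmentError, match="1999"):
            lag_and_standardize(anoms, 1, [2000, 2001])
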