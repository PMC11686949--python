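"""Shared fixtures: lean model configurations and one reusable fit."""

import numpy as np
import pytest

from trophdyn.model import ModelConfig, fit_jdsdm
from trophdyn.synth import recovery_scenario


def lean_config(**kw) -> ModelConfig:
    """Single spatial factor, density-predictor covariates only."""
    base = dict(
        n_factors_spatial=1,
        n_factors_spatiotemporal=0,
        fields_on_predictor2=False,
        covariates_on_predictor2=False,
        year_effects_2="constant",
        include_census_effects=False,  # scenario truth carries no such term
        compute_se=False,
        seed=0,
    )
    base.update(kw)
    return ModelConfig(**base)


@pytest.fixture(scope="session")
def small_scenario():
    """40-site, 8-year, 3-group scenario with covariate effect 0.4."""
    biomass, birds, design, truth = recovery_scenario(
        n_sites=40, n_years=8, n_groups=3, effect=0.4, seed=11
    )
    return biomass, birds, design, truth


@pytest.fixture(scope="session")
def small_fit(small_scenario):
    """One converged fit with standard errors, reused across test modules."""
    biomass, birds, design, _ = small_scenario
    fit = fit_jdsdm(biomass, birds, design, lean_config(compute_se=True))
    assert np.isfinite(fit.marginal_nll)
    return fit
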