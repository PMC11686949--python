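"""Trait-based functional grouping and biomass conversion.

Species-level monitoring counts are converted to fresh biomass and pooled
into functional groups: birds by migratory strategy x reliance on
caterpillars in nestling provisioning (11 populated combinations), moths
by overwintering life stage (larva, adult/egg, pupa) after restricting to
"easy" prey species.  Moth body masses come from a wingspan + body-plan
linear regression fitted to specimen data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

logger = logging.getLogger(__name__)

MIGRATORY_STATUSES = ("RES", "SDM", "LDM")
DIETS = (
    "high_reliance",
    "moderate_reliance",
    "low_reliance",
    "other_invertebrates",
    "plants",
)

#: The 11 populated (migratory status, diet) combinations.  The remaining
#: 4 of the 15 possible combinations contain no study species and are
#: rejected by :func:`classify_bird_group`.
BIRD_GROUPS: dict[tuple[str, str], str] = {
    ("LDM", "high_reliance"): "LDM_HighReliance",
    ("LDM", "moderate_reliance"): "LDM_ModerateReliance",
    ("LDM", "low_reliance"): "LDM_LowReliance",
    ("SDM", "moderate_reliance"): "SDM_ModerateReliance",
    ("SDM", "low_reliance"): "SDM_LowReliance",
    ("SDM", "plants"): "SDM_Plants",
    ("RES", "high_reliance"): "RES_HighReliance",
    ("RES", "moderate_reliance"): "RES_ModerateReliance",
    ("RES", "low_reliance"): "RES_LowReliance",
    ("RES", "other_invertebrates"): "RES_OtherInvertebrates",
    ("RES", "plants"): "RES_Plants",
}

OVERWINTER_STAGES = ("larva", "adult_egg", "pupa")

#: Moth functional groups keyed by overwintering stage.
MOTH_GROUPS: dict[str, str] = {
    "larva": "Larva",
    "adult_egg": "AdultEgg",
    "pupa": "Pupa",
}

#: Floor for predicted specimen mass (mg); predictions below it are clipped.
MIN_PREDICTED_MASS_MG = 0.1


@dataclass(frozen=True)
class BirdTrait:
    """Classification fields for one bird species."""

    species_id: str
    migratory_status: str
    diet: str
    body_mass_g: float

    def __post_init__(self):
        if self.migratory_status not in MIGRATORY_STATUSES:
            raise ValidationError(
                f"unknown migratory status {self.migratory_status!r} for "
                f"{self.species_id}"
            )
        if self.diet not in DIETS:
            raise ValidationError(
                f"unknown diet class {self.diet!r} for {self.species_id}"
            )
        if not self.body_mass_g > 0:
            raise ValidationError(
                f"non-positive body mass for {self.species_id}"
            )


@dataclass(frozen=True)
class MothTrait:
    """Classification fields for one moth species."""

    species_id: str
    overwinter_stage: str
    prey_class: str
    wingspan_mm: float
    body_plan: str

    def __post_init__(self):
        if self.overwinter_stage not in OVERWINTER_STAGES:
            raise ValidationError(
                f"unknown overwintering stage {self.overwinter_stage!r} for "
                f"{self.species_id}"
            )
        if self.prey_class not in ("easy", "difficult"):
            raise ValidationError(
                f"unknown prey class {self.prey_class!r} for {self.species_id}"
            )
        if self.body_plan not in ("stout", "slender"):
            raise ValidationError(
                f"unknown body plan {self.body_plan!r} for {self.species_id}"
            )
        if not self.wingspan_mm > 0:
            raise ValidationError(
                f"non-positive wingspan for {self.species_id}"
            )


@dataclass(frozen=True)
class BodyMassModel:
    """Linear model for fresh body mass (mg) ~ wingspan (mm) + body plan.

    ``stout_offset`` is ``None`` when only one body plan was present in
    the specimen table (reduced design).
    """

    intercept: float
    wingspan_slope: float
    stout_offset: float | None
    residual_sd: float
    n_obs: int

    def predict(self, wingspan_mm, body_plan) -> np.ndarray:
        """Predicted mass (mg); clipped below at MIN_PREDICTED_MASS_MG."""
        wingspan_mm = np.asarray(wingspan_mm, dtype=float)
        if np.any(wingspan_mm <= 0):
            raise ValidationError("wingspan must be positive")
        stout = np.asarray(
            [bp == "stout" for bp in np.atleast_1d(body_plan)], dtype=float
        )
        offset = 0.0 if self.stout_offset is None else self.stout_offset
        pred = self.intercept + self.wingspan_slope * wingspan_mm + offset * stout
        clipped = pred < MIN_PREDICTED_MASS_MG
        if np.any(clipped):
            logger.warning(
                "clipped %d non-positive mass predictions to %.1f mg",
                int(np.sum(clipped)),
                MIN_PREDICTED_MASS_MG,
            )
        return np.maximum(pred, MIN_PREDICTED_MASS_MG)


def fit_bodymass_model(specimens: pd.DataFrame) -> BodyMassModel:
    """Fit the specimen body-mass regression by ordinary least squares.

    Parameters
    ----------
    specimens
        Columns ``wingspan_mm``, ``body_plan`` ("stout"/"slender") and
        ``mass_mg``; one row per specimen.
    """
    required = {"wingspan_mm", "body_plan", "mass_mg"}
    missing = required - set(specimens.columns)
    if missing:
        raise ValidationError(f"specimen table missing columns {sorted(missing)}")
    if len(specimens) < 3:
        raise ValidationError("need at least 3 specimens to fit the model")
    if (specimens["wingspan_mm"] <= 0).any():
        raise ValidationError("wingspan must be positive")
    bad_plan = ~specimens["body_plan"].isin(["stout", "slender"])
    if bad_plan.any():
        raise ValidationError(
            f"unknown body plans: {sorted(specimens.loc[bad_plan, 'body_plan'].unique())}"
        )

    wingspan = specimens["wingspan_mm"].to_numpy(float)
    stout = (specimens["body_plan"] == "stout").to_numpy(float)
    both_plans = 0 < stout.sum() < len(stout)

    cols = [np.ones_like(wingspan), wingspan]
    if both_plans:
        cols.append(stout)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("singular specimen design (collinear columns)")
    if len(specimens) < design.shape[1]:
        raise ValidationError("fewer specimens than regression coefficients")

    fit = sm.OLS(specimens["mass_mg"].to_numpy(float), design).fit()
    resid_sd = float(np.sqrt(fit.scale)) if fit.df_resid > 0 else 0.0
    return BodyMassModel(
        intercept=float(fit.params[0]),
        wingspan_slope=float(fit.params[1]),
        stout_offset=float(fit.params[2]) if both_plans else None,
        residual_sd=resid_sd,
        n_obs=len(specimens),
    )


def bird_counts_to_biomass(pairs, mass_g) -> np.ndarray:
    """Breeding pairs -> individual birds (x2) -> grams (x species mass)."""
    pairs = np.asarray(pairs, dtype=float)
    mass_g = np.asarray(mass_g, dtype=float)
    if np.any(pairs < 0):
        raise ValidationError("pair counts must be non-negative")
    if np.any(mass_g <= 0):
        raise ValidationError("body mass must be positive")
    return pairs * 2.0 * mass_g


def moth_counts_to_biomass(count, trait: MothTrait, model: BodyMassModel) -> float:
    """Trap count of a species -> fresh biomass (mg) via predicted mass."""
    if count < 0:
        raise ValidationError("count must be non-negative")
    mass = float(model.predict(trait.wingspan_mm, trait.body_plan)[0])
    return float(count) * mass


def filter_easy_moths(traits: list[MothTrait]) -> list[MothTrait]:
    """Keep only species classified as 'easy' prey."""
    missing = [t.species_id for t in traits if not t.prey_class]
    if missing:
        raise ValidationError(f"missing prey class for species {missing}")
    return [t for t in traits if t.prey_class == "easy"]


def classify_bird_group(trait: BirdTrait) -> str:
    """Map a bird trait row to its (migratory status, diet) group id."""
    key = (trait.migratory_status, trait.diet)
    if key not in BIRD_GROUPS:
        raise ValidationError(
            f"({trait.migratory_status}, {trait.diet}) is one of the 4 "
            "unpopulated trait combinations; no such functional group"
        )
    return BIRD_GROUPS[key]


def classify_moth_group(trait: MothTrait) -> str:
    """Map a moth trait row to its overwintering-stage group id."""
    if trait.overwinter_stage not in MOTH_GROUPS:
        raise ValidationError(f"unknown stage {trait.overwinter_stage!r}")
    return MOTH_GROUPS[trait.overwinter_stage]


def pool_group_biomass(
    records: pd.DataFrame, grouping: dict[str, str]
) -> pd.DataFrame:
    """Sum species-level biomass into site x year x group totals.

    Parameters
    ----------
    records
        Columns ``site_id``, ``year``, ``species_id``, ``biomass``.
    grouping
        species_id -> group_id map; every species in ``records`` must be
        present.

    Explicit zeros in the input are retained: the output has one row per
    observed site x year x group combination, including zero totals, since
    the delta observation model needs true zeros.
    """
    required = {"site_id", "year", "species_id", "biomass"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"records missing columns {sorted(missing)}")
    unmapped = sorted(set(records["species_id"]) - set(grouping))
    if unmapped:
        raise ValidationError(f"species missing from grouping map: {unmapped}")
    if (records["biomass"] < 0).any():
        raise ValidationError("biomass must be non-negative")

    out = records.copy()
    out["group_id"] = out["species_id"].map(grouping)
    pooled = (
        out.groupby(["site_id", "year", "group_id"], as_index=False)
        .agg(biomass=("biomass", "sum"), n_species_pooled=("species_id", "nunique"))
        .sort_values(["site_id", "year", "group_id"], ignore_index=True)
    )
    return pooled


def filter_trap_longevity(trap_series: pd.DataFrame, min_years: int = 5) -> pd.DataFrame:
    """Keep traps sampled in at least ``min_years`` distinct years.

    ``trap_series`` needs columns ``site_id`` and ``year``; the returned
    frame contains only rows from qualifying traps.
    """
    if min_years < 1:
        raise ValidationError("min_years must be >= 1")
    years_per_trap = trap_series.groupby("site_id")["year"].nunique()
    keep = set(years_per_trap.index[years_per_trap >= min_years])
    dropped = set(years_per_trap.index) - keep
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} trap(s) with < {min_years} sampled years",
            stacklevel=2,
        )
    return trap_series[trap_series["site_id"].isin(keep)].reset_index(drop=True)
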