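"""Scenario configuration for the feeding-trial simulator.

Every tunable of the pipeline lives in :class:`ScenarioConfig`: cohort size
and arm allocation, the macronutrient composition of the three test diets,
the carbohydrate dose-response of total energy expenditure (TEE), the
baseline covariate distributions (calibrated to the marginals of a 145-person
weight-loss-maintenance feeding trial), the measurement-error model for
intake, expenditure and body-fat change, the non-adherence mixture, and the
energetic constants used by the doubly-labeled-water (DLW) layer.

Configurations serialize to YAML or JSON; unknown keys are rejected so a
typo in a scenario file fails loudly rather than silently running defaults.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["DietComposition", "ScenarioConfig", "ConfigurationError", "ARMS", "PIPELINE_STAGES"]

#: Canonical arm labels, ordered by prescribed carbohydrate fraction.
ARMS = ("low", "moderate", "high")

#: Pipeline stages with independently derivable child seeds.
PIPELINE_STAGES = ("simulate", "nonadherence", "ue", "sweep", "table1", "sensitivity")


class ConfigurationError(ValueError):
    """Raised when a scenario configuration violates an invariant."""


class DietComposition(BaseModel):
    """Macronutrient composition of a diet as fractions of total energy."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    carb_fraction: float = Field(ge=0.0, le=1.0)
    fat_fraction: float = Field(ge=0.0, le=1.0)
    protein_fraction: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "DietComposition":
        total = self.carb_fraction + self.fat_fraction + self.protein_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"diet composition fractions must sum to 1, got {total!r}"
            )
        return self


class ScenarioConfig(BaseModel):
    """All parameters of a simulated feeding-trial scenario.

    Defaults encode the study conditions the toolkit is calibrated to:
    145 participants randomized 1:1:1 to 20/40/60%-carbohydrate diets for
    weight-loss maintenance after a ~10.5% run-in loss, a low-vs-high TEE
    effect of 250 kcal/d at the 82-kg reference weight, and measurement
    errors consistent with doubly-labeled-water precision.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # -- cohort structure -------------------------------------------------
    n_participants: int = Field(default=145, ge=6)
    arm_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    diet_low: DietComposition = DietComposition(
        carb_fraction=0.20, fat_fraction=0.60, protein_fraction=0.20
    )
    diet_moderate: DietComposition = DietComposition(
        carb_fraction=0.40, fat_fraction=0.40, protein_fraction=0.20
    )
    diet_high: DietComposition = DietComposition(
        carb_fraction=0.60, fat_fraction=0.20, protein_fraction=0.20
    )

    #: kcal/d of extra TEE per 10% absolute decrease in dietary carbohydrate,
    #: at the reference body weight.  62.5 kcal/d per 10% makes the
    #: low-vs-high (20% vs 60%) contrast 250 kcal/d, the study-scale effect.
    cim_slope: float = Field(default=62.5)

    # -- baseline covariate distributions ---------------------------------
    female_fraction: float = Field(default=0.69, ge=0.0, le=1.0)
    age_median: float = Field(default=35.7, gt=0)
    age_log_sd: float = Field(default=0.5586, ge=0)
    weight_mean_kg: float = Field(default=91.3, gt=0)
    weight_sd_kg: float = Field(default=18.3, ge=0)
    #: male-minus-female mean weight gap, kg (marginal mean/SD preserved).
    weight_male_shift: float = Field(default=14.0, ge=0)
    height_mean_cm: float = Field(default=168.0, gt=0)
    height_sd_cm: float = Field(default=10.1, ge=0)
    #: male-minus-female mean height gap, cm.
    height_male_shift: float = Field(default=13.0, ge=0)
    insulin30_median: float = Field(default=113.5, gt=0)
    insulin30_log_sd: float = Field(default=0.5838, ge=0)
    #: Gaussian-copula correlation between insulin-30 and body weight.
    insulin30_weight_corr: float = Field(default=0.3, ge=-1.0, le=1.0)
    bodyfat_female_mean: float = Field(default=43.6, gt=0)
    bodyfat_male_mean: float = Field(default=34.0, gt=0)
    bodyfat_sd: float = Field(default=5.0, ge=0)
    race_fractions: tuple[float, float, float, float] = (0.786, 0.103, 0.034, 0.077)
    hispanic_fraction: float = Field(default=0.145, ge=0.0, le=1.0)
    n_cohorts: int = Field(default=3, ge=1)
    runin_loss_mean_pct: float = Field(default=10.5)
    runin_loss_sd_pct: float = Field(default=1.6, ge=0)
    #: kcal/d of run-in % loss explained per SD of baseline TEE (negative:
    #: higher-expenditure participants achieved less relative loss).
    runin_tee_slope: float = Field(default=-1.0)

    # -- baseline TEE model (pre-weight-loss, kcal/d) ---------------------
    tee_mean: float = Field(default=3008.0, gt=0)
    tee_sd: float = Field(default=718.0, gt=0)
    tee_male_coef: float = 200.0
    tee_weight_coef: float = 28.0
    tee_height_coef: float = 8.0
    tee_age_coef: float = -4.0
    tee_resid_sd: float = Field(default=410.0, ge=0)

    #: Adaptive decline of maintenance TEE, kcal/d per percent run-in loss
    #: (absolute, not proportional to size).
    adaptive_drop_per_pct: float = Field(default=29.0, ge=0)

    # -- measurement-error model ------------------------------------------
    #: SDs at unit error scale; each participant's SDs are multiplied by
    #: their energy-flux scale (maintenance TEE / its mean), floored below.
    sd_tee: float = Field(default=160.0, ge=0)
    sd_ei: float = Field(default=100.0, ge=0)
    sd_dfm: float = Field(default=0.003, ge=0)
    sd_subject: float = Field(default=50.0, ge=0)
    error_scale_floor: float = Field(default=0.4, gt=0)
    #: Fraction of true consumed energy missing from measured intake
    #: (provision-side accounting gap of a controlled feeding study).
    intake_underreport: float = Field(default=0.18, ge=0.0, lt=1.0)
    #: Fraction of the diet-induced TEE change tracked by measured intake.
    intake_tracking: float = Field(default=0.5, ge=0.0, le=1.0)
    #: Optional SD of true energy imbalance around weight maintenance.
    maintenance_noise_sd: float = Field(default=0.0, ge=0)
    #: Optional missing-completely-at-random rate for measured TEE.
    missing_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    # -- non-adherence mixture --------------------------------------------
    nonadherence_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    #: Proportion of the gap toward 40% carbohydrate closed by
    #: non-adherent eaters ("conservative" default: halfway).
    nonadherence_drift: float = Field(default=0.5, ge=0.0, le=1.0)

    # -- energetic constants ----------------------------------------------
    rho_fm: float = Field(default=9441.0, gt=0)  # kcal per kg fat-mass change
    #: Optional energy density for a fat-free-mass correction term in UE
    #: (kcal/kg); disabled by default to match the fat-mass-only definition.
    rho_ffm: float | None = None
    weir_o2: float = Field(default=3.941, gt=0)  # kcal per liter O2
    weir_co2: float = Field(default=1.106, gt=0)  # kcal per liter CO2
    rq_carb: float = Field(default=1.000, ge=0.6, le=1.1)
    rq_fat: float = Field(default=0.710, ge=0.6, le=1.1)
    rq_protein: float = Field(default=0.835, ge=0.6, le=1.1)

    # -- analysis conventions ----------------------------------------------
    reference_weight_kg: float = Field(default=82.0, gt=0)
    n_quantile_bins: int = Field(default=36, ge=2)
    ue_timepoint: Literal["final", "mean"] = "final"

    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_invariants(self) -> "ScenarioConfig":
        if abs(sum(self.arm_fractions) - 1.0) > 1e-9:
            raise ValueError(f"arm_fractions must sum to 1, got {self.arm_fractions}")
        if any(f < 0 for f in self.arm_fractions):
            raise ValueError("arm_fractions must be non-negative")
        if abs(sum(self.race_fractions) - 1.0) > 1e-9:
            raise ValueError("race_fractions must sum to 1")
        return self

    # -- derived quantities ------------------------------------------------

    @property
    def diets(self) -> dict[str, DietComposition]:
        return {
            "low": self.diet_low,
            "moderate": self.diet_moderate,
            "high": self.diet_high,
        }

    def arm_effect(self, arm: str) -> float:
        """Programmed TEE effect of *arm* vs the 40%-carbohydrate anchor,
        in kcal/d at the reference body weight."""
        carb = self.diets[arm].carb_fraction
        return self.cim_slope * (0.40 - carb) / 0.10

    def noise_free(self) -> "ScenarioConfig":
        """A copy with every measurement-error mechanism switched off.

        Zeroes all error SDs and the systematic intake-accounting gap, and
        sets intake tracking to 1, so measured quantities equal the truth
        and unaccounted energy is identically zero under full adherence.
        """
        return self.model_copy(
            update=dict(
                sd_tee=0.0,
                sd_ei=0.0,
                sd_dfm=0.0,
                sd_subject=0.0,
                maintenance_noise_sd=0.0,
                intake_underreport=0.0,
                intake_tracking=1.0,
                missing_rate=0.0,
            )
        )

    # -- seeding -----------------------------------------------------------

    def child_seed(self, stage: str, replicate: int = 0) -> np.random.SeedSequence:
        """Deterministic per-stage (and per-replicate) seed derived from the
        master seed, so any stage can be replayed in isolation."""
        if stage not in PIPELINE_STAGES:
            raise ConfigurationError(f"unknown pipeline stage {stage!r}")
        return np.random.SeedSequence(
            entropy=self.seed, spawn_key=(PIPELINE_STAGES.index(stage), replicate)
        )

    def child_rng(self, stage: str, replicate: int = 0) -> np.random.Generator:
        return np.random.default_rng(self.child_seed(stage, replicate))

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        """Load a configuration from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        try:
            return cls.model_validate(data)
        except Exception as exc:  # re-raise with a uniform type for the CLI
            raise ConfigurationError(str(exc)) from exc

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))

    def validated(self) -> "ScenarioConfig":
        """Return self after re-running all invariant checks."""
        try:
            return self.model_validate(self.model_dump())
        except Exception as exc:
            raise ConfigurationError(str(exc)) from exc
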