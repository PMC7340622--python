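"""Synthetic feeding-trial cohorts with latent truth.

The generator produces one row per participant with both the *true* and the
*measured* energetics of a three-arm (20/40/60% carbohydrate) weight-loss-
maintenance trial, so that the bias introduced by post-randomization
exclusion can be measured directly against the latent truth.

Structure of a participant record
---------------------------------
Baseline covariates are drawn from distributions matched to the marginals
of the emulated trial (n=145, 69% female, weight 91.3 +/- 18.3 kg, baseline
TEE 3008 +/- 718 kcal/d, run-in loss 10.5 +/- 1.6%).  Pre-weight-loss TEE is
linear in sex, weight, height and age; maintenance TEE after the run-in is
the baseline minus an adaptive drop proportional to the percent weight lost.
The prescribed diet adds a dose-response effect of ``cim_slope`` kcal/d per
10% carbohydrate decrease, scaled by post-loss weight relative to the 82-kg
reference (so the weight-normalized effect is constant across body sizes).

Measurement errors on intake, expenditure and fat-mass change are
independent Gaussians whose SDs scale with the participant's energy flux
(maintenance TEE relative to its mean): larger people have larger absolute
errors, which is what links "unaccounted energy" to baseline covariates.
Measured intake additionally carries a systematic accounting gap
(``intake_underreport``) and tracks only ``intake_tracking`` of the
diet-induced TEE change, since provision records are anchored to
maintenance requirements.

Non-adherent eaters drift toward the 40%-carbohydrate diet: their true
effect shrinks accordingly and their true RQ diverges from the assumed food
quotient, which the DLW stage converts into a multiplicative TEE
measurement bias (see :mod:`exclusim.dlw`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ARMS, ScenarioConfig

__all__ = ["sample_cohort", "apply_nonadherence", "rebuild_measurements",
           "COLUMN_DICTIONARY", "write_cohort", "read_cohort"]

RACE_LEVELS = ("white", "black", "asian", "other")

#: Documented meaning of every CohortTable column (one row per participant).
COLUMN_DICTIONARY: dict[str, str] = {
    "id": "participant identifier (0-based, stable across stages)",
    "arm": "assigned diet arm: low / moderate / high carbohydrate",
    "female": "1 if female",
    "age": "age at baseline, years",
    "weight": "pre-weight-loss body weight, kg",
    "height": "height, cm",
    "bmi": "weight / height^2, kg/m^2",
    "bodyfat_pct": "baseline body fat by DXA, percent",
    "race": "race category (white/black/asian/other)",
    "hispanic": "1 if Hispanic",
    "insulin30": "insulin 30 min post glucose load, uIU/ml",
    "cohort": "enrollment cohort index, 1..n_cohorts",
    "runin_loss": "run-in weight loss, percent of baseline weight",
    "weight_postloss": "post-run-in weight, kg",
    "tee_baseline_true": "true pre-weight-loss TEE, kcal/d",
    "tee_baseline_measured": "DLW-measured pre-weight-loss TEE, kcal/d",
    "tee_maintenance_true": "true post-loss maintenance TEE (no diet effect), kcal/d",
    "effect_prescribed": "programmed TEE effect of the assigned diet, kcal/d",
    "effect_consumed": "TEE effect of the diet actually consumed, kcal/d",
    "carb_prescribed": "prescribed carbohydrate energy fraction",
    "carb_consumed": "consumed carbohydrate energy fraction",
    "rq_assumed": "food quotient of the prescribed diet (DLW assumption)",
    "rq_true": "food quotient of the consumed diet",
    "rq_bias": "apparent/true TEE ratio induced by the RQ divergence",
    "adherent": "1 if adherent to the prescribed diet",
    "subject_intercept": "latent test-phase biological TEE offset, kcal/d",
    "tee_true_mid": "true TEE at test-phase midpoint, kcal/d",
    "tee_true_end": "true TEE at test-phase end, kcal/d",
    "tee_measured_mid": "measured TEE at midpoint, kcal/d",
    "tee_measured_end": "measured TEE at end, kcal/d",
    "ei_true_mid": "true energy intake at midpoint, kcal/d",
    "ei_true_end": "true energy intake at end, kcal/d",
    "ei_measured_mid": "measured energy intake at midpoint, kcal/d",
    "ei_measured_end": "measured energy intake at end, kcal/d",
    "ei_measured_start": "measured energy intake at start of test phase, kcal/d",
    "dfm_true": "true fat-mass change rate over the test phase, kg/d",
    "dfm_measured": "measured fat-mass change rate, kg/d",
    "tee_err_baseline": "latent baseline TEE measurement error, kcal/d",
    "tee_err_mid": "latent midpoint TEE measurement error, kcal/d",
    "tee_err_end": "latent end TEE measurement error, kcal/d",
    "ei_err_mid": "latent midpoint intake measurement noise, kcal/d",
    "ei_err_end": "latent end intake measurement noise, kcal/d",
    "ei_err_start": "latent start-of-test intake measurement noise, kcal/d",
    "dfm_err": "latent fat-mass-change measurement error, kg/d",
    "error_scale": "participant's energy-flux error scale (dimensionless)",
    "maintenance_noise": "latent true energy imbalance at maintenance, kcal/d",
}


def _allocate_arms(n: int, fractions, rng: np.random.Generator) -> np.ndarray:
    """Stratified allocation: fixed counts per arm, randomly interleaved."""
    counts = [int(np.floor(f * n)) for f in fractions]
    # distribute the remainder to the largest fractional parts
    rem = n - sum(counts)
    fracs = [f * n - np.floor(f * n) for f in fractions]
    for i in np.argsort(fracs)[::-1][:rem]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(fractions)), counts)
    rng.shuffle(labels)
    return labels


def sample_cohort(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate a cohort table under the given scenario.

    Deterministic given ``(config, seed)``; when *seed* is omitted the
    config's master seed drives the 'simulate' stage.  Non-adherence is
    applied automatically when ``config.nonadherence_fraction > 0``.
    """
    config = config.validated()
    if seed is None:
        rng = config.child_rng("simulate")
    else:
        rng = np.random.default_rng(seed)
    n = config.n_participants

    arm_idx = _allocate_arms(n, config.arm_fractions, rng)
    arm = np.array(ARMS)[arm_idx]

    female = rng.random(n) < config.female_fraction
    male_c = (~female) - (1.0 - config.female_fraction)  # centered male indicator
    age = np.exp(rng.normal(np.log(config.age_median), config.age_log_sd, n))
    # sex-shifted anthropometrics with the overall marginal mean/SD preserved
    pq = config.female_fraction * (1.0 - config.female_fraction)
    w_resid = np.sqrt(max(config.weight_sd_kg**2 - pq * config.weight_male_shift**2, 0.0))
    h_resid = np.sqrt(max(config.height_sd_cm**2 - pq * config.height_male_shift**2, 0.0))
    weight = np.clip(
        config.weight_mean_kg + config.weight_male_shift * male_c
        + rng.normal(0.0, w_resid, n), 45.0, None)
    height = np.clip(
        config.height_mean_cm + config.height_male_shift * male_c
        + rng.normal(0.0, h_resid, n), 140.0, None)
    z_weight = (weight - config.weight_mean_kg) / max(config.weight_sd_kg, 1e-12)
    r = config.insulin30_weight_corr
    z_ins = r * z_weight + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n)
    insulin30 = np.exp(np.log(config.insulin30_median) + config.insulin30_log_sd * z_ins)
    bodyfat = np.where(female, config.bodyfat_female_mean, config.bodyfat_male_mean)
    bodyfat = np.clip(bodyfat + rng.normal(0.0, config.bodyfat_sd, n), 10.0, 65.0)
    race = rng.choice(RACE_LEVELS, size=n, p=config.race_fractions)
    hispanic = rng.random(n) < config.hispanic_fraction
    cohort = rng.integers(1, config.n_cohorts + 1, n)

    # pre-weight-loss TEE: linear model, intercept solved for the target mean
    male = ~female
    mean_age = config.age_median * np.exp(config.age_log_sd**2 / 2)
    intercept = config.tee_mean - config.tee_male_coef * (1.0 - config.female_fraction)
    tee_baseline_true = (
        intercept
        + config.tee_male_coef * male
        + config.tee_weight_coef * (weight - config.weight_mean_kg)
        + config.tee_height_coef * (height - config.height_mean_cm)
        + config.tee_age_coef * (age - mean_age)
        + rng.normal(0.0, config.tee_resid_sd, n)
    )
    tee_baseline_true = np.clip(tee_baseline_true, 1200.0, None)
    z_tee = (tee_baseline_true - config.tee_mean) / config.tee_sd

    resid_sd = np.sqrt(max(config.runin_loss_sd_pct**2 - config.runin_tee_slope**2, 0.0))
    runin = (
        config.runin_loss_mean_pct
        + config.runin_tee_slope * z_tee
        + rng.normal(0.0, resid_sd, n)
    )
    runin = np.clip(runin, 0.0, 30.0)

    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "arm": arm,
            "female": female.astype(int),
            "age": age,
            "weight": weight,
            "height": height,
            "bmi": weight / (height / 100.0) ** 2,
            "bodyfat_pct": bodyfat,
            "race": race,
            "hispanic": hispanic.astype(int),
            "insulin30": insulin30,
            "cohort": cohort,
            "runin_loss": runin,
            "weight_postloss": weight * (1.0 - runin / 100.0),
            "tee_baseline_true": tee_baseline_true,
            "adherent": np.ones(n, dtype=int),
        }
    )

    # latent error draws (kept so later stages are pure re-derivations)
    scale = np.clip(
        (tee_baseline_true - config.adaptive_drop_per_pct * runin)
        / (config.tee_mean - config.adaptive_drop_per_pct * config.runin_loss_mean_pct),
        config.error_scale_floor,
        None,
    )
    df["error_scale"] = scale
    df["subject_intercept"] = rng.normal(0.0, config.sd_subject * scale)
    df["tee_err_baseline"] = rng.normal(0.0, config.sd_tee * scale)
    df["tee_err_mid"] = rng.normal(0.0, config.sd_tee * scale)
    df["tee_err_end"] = rng.normal(0.0, config.sd_tee * scale)
    df["ei_err_start"] = rng.normal(0.0, config.sd_ei * scale)
    df["ei_err_mid"] = rng.normal(0.0, config.sd_ei * scale)
    df["ei_err_end"] = rng.normal(0.0, config.sd_ei * scale)
    df["dfm_err"] = rng.normal(0.0, config.sd_dfm * scale)
    df["maintenance_noise"] = (
        rng.normal(0.0, config.maintenance_noise_sd, n)
        if config.maintenance_noise_sd > 0
        else np.zeros(n)
    )

    # consumed diet starts as prescribed
    carb_presc = np.array([config.diets[a].carb_fraction for a in arm])
    df["carb_prescribed"] = carb_presc
    df["carb_consumed"] = carb_presc.copy()

    df = rebuild_measurements(df, config)

    if config.missing_rate > 0:
        miss = rng.random(n) < config.missing_rate
        df.loc[miss, ["tee_measured_mid", "tee_measured_end"]] = np.nan

    if config.nonadherence_fraction > 0:
        df = apply_nonadherence(df, config)
    return df


def rebuild_measurements(cohort: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Re-derive all true and measured energetics from latent components.

    Called after sampling and again after adherence changes; everything
    downstream of the latent draws is a deterministic function of them, so
    stages can edit the consumed diet and simply rebuild.
    """
    df = cohort.copy()
    wpost = df["weight_postloss"].to_numpy()
    runin = df["runin_loss"].to_numpy()
    teeB = df["tee_baseline_true"].to_numpy()

    maintenance = teeB - config.adaptive_drop_per_pct * runin
    df["tee_maintenance_true"] = maintenance

    size_factor = wpost / config.reference_weight_kg
    carb_p = df["carb_prescribed"].to_numpy()
    carb_c = df["carb_consumed"].to_numpy()
    df["effect_prescribed"] = config.cim_slope * (0.40 - carb_p) / 0.10 * size_factor
    df["effect_consumed"] = config.cim_slope * (0.40 - carb_c) / 0.10 * size_factor

    # food quotients: consumed diet keeps the prescribed protein fraction,
    # carbohydrate displaces fat
    fq_kw = dict(rq_carb=config.rq_carb, rq_fat=config.rq_fat, rq_protein=config.rq_protein)
    prot = np.array([config.diets[a].protein_fraction for a in df["arm"]])
    rq_assumed = config.rq_carb * carb_p + config.rq_fat * (1 - carb_p - prot) + config.rq_protein * prot
    rq_true = config.rq_carb * carb_c + config.rq_fat * (1 - carb_c - prot) + config.rq_protein * prot
    del fq_kw
    df["rq_assumed"] = rq_assumed
    df["rq_true"] = rq_true
    df["rq_bias"] = (config.weir_o2 / rq_assumed + config.weir_co2) / (
        config.weir_o2 / rq_true + config.weir_co2
    )

    eff = df["effect_consumed"].to_numpy()
    b = df["subject_intercept"].to_numpy()
    tee_true = maintenance + eff + b
    df["tee_true_mid"] = tee_true
    df["tee_true_end"] = tee_true

    # weight maintenance: true intake equals true expenditure (+ optional noise)
    mnoise = df["maintenance_noise"].to_numpy()
    df["ei_true_mid"] = tee_true + mnoise
    df["ei_true_end"] = tee_true + mnoise
    df["dfm_true"] = mnoise / config.rho_fm  # energy conservation

    bias = df["rq_bias"].to_numpy()
    df["tee_baseline_measured"] = teeB + df["tee_err_baseline"].to_numpy()
    df["tee_measured_mid"] = tee_true * bias + df["tee_err_mid"].to_numpy()
    df["tee_measured_end"] = tee_true * bias + df["tee_err_end"].to_numpy()

    # measured intake: provision records anchored at maintenance requirement,
    # partially tracking the diet effect, with a systematic accounting gap
    gamma = config.intake_underreport
    theta = config.intake_tracking
    provision = (1.0 - gamma) * (maintenance + theta * eff + mnoise)
    df["ei_measured_start"] = (1.0 - gamma) * maintenance + df["ei_err_start"].to_numpy()
    df["ei_measured_mid"] = provision + df["ei_err_mid"].to_numpy()
    df["ei_measured_end"] = provision + df["ei_err_end"].to_numpy()

    df["dfm_measured"] = df["dfm_true"] + df["dfm_err"]
    return df


def apply_nonadherence(cohort: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Flag non-adherent participants and rebuild their energetics.

    Exactly ``round(fraction * n_arm)`` participants per arm are flagged;
    their consumed carbohydrate moves ``nonadherence_drift`` of the way
    toward 40% of energy.  Selection uses the 'nonadherence' child seed of
    the config, so the operation is deterministic given the config.
    """
    config = config.validated()
    frac = config.nonadherence_fraction
    df = cohort.copy()
    df["adherent"] = 1
    df["carb_consumed"] = df["carb_prescribed"]
    if frac > 0:
        rng = config.child_rng("nonadherence")
        drift = config.nonadherence_drift
        for a in ARMS:
            idx = df.index[df["arm"] == a].to_numpy()
            k = int(round(frac * len(idx)))
            picked = rng.choice(idx, size=k, replace=False)
            df.loc[picked, "adherent"] = 0
            carb = df.loc[picked, "carb_prescribed"]
            df.loc[picked, "carb_consumed"] = carb + drift * (0.40 - carb)
    return rebuild_measurements(df, config)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (lossless round trip to 1e-9)."""
    cohort.to_csv(path, index=False, float_format="%.12g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
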