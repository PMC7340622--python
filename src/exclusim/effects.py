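"""Diet-effect estimation on TEE change, unadjusted and covariate-adjusted.

The outcome is the change in DLW-measured TEE from the pre-weight-loss
baseline to the test phase, averaged over the two test-phase timepoints.
With two balanced timepoints, no timepoint-by-arm interaction, and a
compound-symmetry within-subject covariance, the between-subject diet
contrast from the repeated-measures model equals the ordinary least-squares
contrast on subject means, which is what is fitted here.

Two estimators are exposed through one entry point:

* ``adjusted=False`` - the plain kcal/d diet effect (arm fixed effects
  only), emulating the exclusion reanalysis as originally run;
* ``adjusted=True`` - TEE change normalized to the 82-kg reference
  post-weight-loss weight (kcal/d per 82 kg) with fixed effects for sex,
  age, baseline weight, height, run-in percent loss, baseline TEE,
  log insulin-30, and enrollment cohort, emulating the covariate-adjusted
  reanalysis.

The reported contrast is always low- minus high-carbohydrate arm; the
moderate arm contributes to residual variance but not to the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import ScenarioConfig

__all__ = ["EffectEstimate", "normalize_tee_change", "fit_diet_effect",
           "ADJUSTMENT_COVARIATES"]

#: Covariate roster of the adjusted model, in design-matrix order.
ADJUSTMENT_COVARIATES = (
    "female", "age", "weight", "height", "runin_loss",
    "tee_baseline_measured", "log_insulin30", "cohort",
)


@dataclass(frozen=True)
class EffectEstimate:
    """Low-vs-high-carbohydrate diet effect on TEE change."""

    estimate: float  # kcal/d (low minus high)
    se: float
    p_value: float
    n_used: int
    adjusted: bool
    covariates: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return asdict(self)


def normalize_tee_change(delta_tee, weight_postloss, reference_weight: float = 82.0):
    """Scale a TEE change to the reference post-weight-loss body weight."""
    w = np.asarray(weight_postloss, dtype=float)
    if np.any(w <= 0) or reference_weight <= 0:
        raise ValueError("weights must be positive")
    out = np.asarray(delta_tee, dtype=float) / w * reference_weight
    return out if out.ndim else float(out)


def subject_outcomes(cohort: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Per-subject mean TEE change (raw and weight-normalized), NaN-free."""
    df = cohort.copy()
    delta = (
        (df["tee_measured_mid"] + df["tee_measured_end"]) / 2.0
        - df["tee_baseline_measured"]
    )
    df["delta_tee"] = delta
    df["delta_tee_norm"] = normalize_tee_change(
        delta, df["weight_postloss"], config.reference_weight_kg
    )
    return df.dropna(subset=["delta_tee"])


def _design(df: pd.DataFrame, adjusted: bool,
            extra: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    n = len(df)
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["arm_low"] = (df["arm"] == "low").astype(float)
    X["arm_moderate"] = (df["arm"] == "moderate").astype(float)
    if adjusted:
        X["female"] = df["female"].astype(float)
        X["age"] = df["age"]
        X["weight"] = df["weight"]
        X["height"] = df["height"]
        X["runin_loss"] = df["runin_loss"]
        X["tee_baseline_measured"] = df["tee_baseline_measured"]
        X["log_insulin30"] = np.log(df["insulin30"])
        for c in sorted(df["cohort"].unique())[1:]:
            X[f"cohort_{c}"] = (df["cohort"] == c).astype(float)
    if extra:
        for name, col in extra.items():
            X[name] = col
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if n <= X.shape[1]:
        raise ValueError(f"too few observations ({n}) for {X.shape[1]} parameters")
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = []
    kept: list[str] = []
    M = np.empty((len(X), 0))
    for name in X.columns:
        cand = np.column_stack([M, X[name].to_numpy()])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            M = cand
            kept.append(name)
        else:
            cols.append(name)
    return cols


def _check_arms(df: pd.DataFrame) -> None:
    counts = df["arm"].value_counts()
    present = [a for a in ("low", "high") if counts.get(a, 0) > 0]
    if len(present) < 2:
        raise ValueError("subset must contain both the low and high arm")
    small = [a for a in counts.index if counts[a] < 3]
    if any(a in ("low", "high") for a in small):
        raise ValueError(f"arm(s) {small} have fewer than 3 participants")


def fit_diet_effect(
    cohort_subset: pd.DataFrame,
    adjusted: bool,
    config: ScenarioConfig,
    per_protocol: bool = False,
) -> EffectEstimate:
    """Estimate the low-vs-high diet effect on TEE change for any subset.

    Intention-to-treat by default: everyone is analyzed per assigned arm
    regardless of adherence.  ``per_protocol=True`` first drops
    non-adherent participants.
    """
    df = cohort_subset
    if per_protocol and "adherent" in df.columns:
        df = df[df["adherent"] == 1]
    df = subject_outcomes(df, config)
    _check_arms(df)
    y = df["delta_tee_norm"] if adjusted else df["delta_tee"]
    X = _design(df, adjusted)
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index("arm_low")
    est = float(res.params[i])
    se = float(res.bse[i])
    p = float(res.pvalues[i])
    covs = tuple(c for c in X.columns if c not in ("const", "arm_low", "arm_moderate"))
    return EffectEstimate(
        estimate=est, se=se, p_value=p, n_used=int(len(df)),
        adjusted=adjusted, covariates=covs,
    )


def fit_group_interaction(
    cohort: pd.DataFrame, config: ScenarioConfig
) -> tuple[EffectEstimate, EffectEstimate, float]:
    """Adjusted diet effect within the low- and high-UE halves, plus the
    two-sided p-value of the group-by-diet interaction.

    The interaction model augments the adjusted design with a ``ue_group``
    main effect and its products with the arm indicators; the reported p is
    for the difference of the low-vs-high contrast between UE groups.
    """
    if "ue_group" not in cohort.columns:
        raise ValueError("cohort has no ue_group column; run the UE stage first")
    groups = set(cohort["ue_group"].unique())
    if groups != {"low", "high"}:
        raise ValueError(f"need both UE groups, got {sorted(groups)}")

    per_group = {}
    for g in ("low", "high"):
        per_group[g] = fit_diet_effect(cohort[cohort["ue_group"] == g], True, config)

    df = subject_outcomes(cohort, config)
    _check_arms(df)
    hi = (df["ue_group"] == "high").astype(float).to_numpy()
    extra = {
        "ue_high": hi,
        "ue_high_x_arm_low": hi * (df["arm"] == "low").to_numpy(),
        "ue_high_x_arm_moderate": hi * (df["arm"] == "moderate").to_numpy(),
    }
    X = _design(df, adjusted=True, extra=extra)
    res = sm.OLS(df["delta_tee_norm"].to_numpy(), X.to_numpy()).fit()
    i = list(X.columns).index("ue_high_x_arm_low")
    p_inter = float(res.pvalues[i])
    return per_group["low"], per_group["high"], p_inter
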