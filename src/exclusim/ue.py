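"""The "Unaccounted Energy" statistic, median split, and quantile bins.

UE is the absolute gap in a participant's energy budget: measured intake
minus measured expenditure, corrected for the energy stored in (or released
from) body fat,

    UE = | EI - TEE - rho_fm * dFM |     (kcal/d, dFM in kg/d),

with rho_fm = 9441 kcal per kg of fat-mass change.  A large UE has been
read as evidence of diet non-adherence, but it equally reflects cumulative
measurement error in any of its three components - which is what makes
excluding on it hazardous.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import ScenarioConfig

__all__ = [
    "compute_ue",
    "dichotomize_by_median",
    "assign_quantile_bins",
    "add_ue_columns",
]


def compute_ue(ei, tee, dfm_rate, rho_fm: float = 9441.0,
               dffm_rate=None, rho_ffm: float | None = None):
    """Unaccounted energy in kcal/d.

    Parameters are scalars or aligned arrays; time-averaging across
    test-phase timepoints, where wanted, happens before this call.  The
    optional fat-free-mass term (``dffm_rate``, ``rho_ffm``) extends the
    stores correction and is off by default.
    """
    if rho_fm <= 0:
        raise ValueError("rho_fm must be positive")
    ei = np.asarray(ei, dtype=float)
    tee = np.asarray(tee, dtype=float)
    dfm = np.asarray(dfm_rate, dtype=float)
    interior = ei - tee - rho_fm * dfm
    if dffm_rate is not None:
        if rho_ffm is None or rho_ffm <= 0:
            raise ValueError("rho_ffm must be positive when dffm_rate is given")
        interior = interior - rho_ffm * np.asarray(dffm_rate, dtype=float)
    out = np.abs(interior)
    return out if out.ndim else float(out)


def dichotomize_by_median(ue_values) -> tuple[np.ndarray, float]:
    """Split at the sample median: values <= median go to the 'low' group.

    With an odd number of distinct values the median participant lands in
    the low group, giving the 73/72 split at n = 145.  Returns the labels
    ('low'/'high') and the median.
    """
    ue = np.asarray(ue_values, dtype=float)
    if ue.size < 2:
        raise ValueError("need at least 2 UE values to dichotomize")
    med = float(np.median(ue))
    labels = np.where(ue <= med, "low", "high")
    if (labels == "high").sum() == 0:
        warnings.warn("degenerate UE distribution: high-UE group is empty")
    return labels, med


def assign_quantile_bins(ue_values, n_bins: int = 36, ids=None) -> np.ndarray:
    """Assign 1-based quantile bins by *descending* UE (bin 1 = highest).

    Bin b holds ranks (round((b-1) n / n_bins), round(b n / n_bins)], so bin
    sizes differ by at most one.  Ties are broken by participant id
    (ascending), making the assignment stable and permutation-invariant up
    to that rule.
    """
    ue = np.asarray(ue_values, dtype=float)
    n = ue.size
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} values, got {n}")
    if ids is None:
        ids = np.arange(n)
    order = np.lexsort((np.asarray(ids), -ue))  # descending UE, id breaks ties
    edges = [int(round(b * n / n_bins)) for b in range(n_bins + 1)]
    bins = np.empty(n, dtype=int)
    for b in range(n_bins):
        bins[order[edges[b]:edges[b + 1]]] = b + 1
    return bins


def add_ue_columns(cohort: pd.DataFrame, config: ScenarioConfig) -> pd.DataFrame:
    """Append ``ue``, ``ue_group`` and ``ue_bin`` columns to a cohort table.

    By default UE is computed from the final test-phase measurements
    (``config.ue_timepoint == 'final'``); the time-averaged variant is
    available as ``'mean'``.  The fat-mass-change rate is a single
    test-phase quantity either way.
    """
    df = cohort.copy()
    if config.ue_timepoint == "final":
        ei = df["ei_measured_end"]
        tee = df["tee_measured_end"]
    else:
        ei = (df["ei_measured_mid"] + df["ei_measured_end"]) / 2.0
        tee = (df["tee_measured_mid"] + df["tee_measured_end"]) / 2.0
    df["ue"] = compute_ue(ei, tee, df["dfm_measured"], rho_fm=config.rho_fm)
    labels, med = dichotomize_by_median(df["ue"].to_numpy())
    df["ue_group"] = labels
    df.attrs["ue_median"] = med
    df["ue_bin"] = assign_quantile_bins(
        df["ue"].to_numpy(), config.n_quantile_bins, ids=df["id"].to_numpy()
    )
    return df
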