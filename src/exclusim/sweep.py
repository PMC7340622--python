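"""Sequential quantile exclusion on unaccounted energy.

The central procedure: rank participants into ``n_quantile_bins`` (default
36) quantile bins of UE, then for k = 0..18 drop bins 1..k (the highest-UE
bins, so k = 18 removes half the cohort) and re-estimate the diet effect
with both estimators on what remains.  Attenuation at step k is

    1 - estimate_k / estimate_0,

always within-estimator.  Bins are computed once on the full cohort and
frozen for the whole sweep.

A deliberate omission: successive sweep estimates share most of their data,
so no trend line or regression across sweep points is fitted or reported
anywhere in this module - only the raw curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .effects import EffectEstimate, fit_diet_effect, fit_group_interaction

__all__ = ["SweepResult", "sequential_exclusion", "compare_extreme_groups"]


@dataclass
class SweepResult:
    """One row per exclusion step k, plus run metadata."""

    table: pd.DataFrame
    max_excluded: int
    per_protocol: bool

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def plot(self, path=None):
        """Attenuation curves for both estimators (no fitted trend)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.table
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(t["k"], 100 * t["attenuation_unadjusted"], "o-", label="unadjusted")
        ax.plot(t["k"], 100 * t["attenuation_adjusted"], "s-", label="covariate-adjusted")
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("highest-UE quantile bins excluded (k)")
        ax.set_ylabel("attenuation of diet effect (%)")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path)
            plt.close(fig)
        return fig


def sequential_exclusion(
    cohort: pd.DataFrame,
    config: ScenarioConfig,
    max_excluded: int | None = None,
    per_protocol: bool = False,
) -> SweepResult:
    """Run the exclusion sweep on a cohort with assigned UE bins.

    Steps whose subset can no longer support an estimator (an arm emptied,
    a rank-deficient design) are recorded as undefined with the reason and
    the sweep continues.
    """
    if "ue_bin" not in cohort.columns:
        raise ValueError("cohort has no ue_bin column; run the UE stage first")
    if max_excluded is None:
        max_excluded = config.n_quantile_bins // 2
    rows = []
    base: dict[bool, EffectEstimate] = {}
    for k in range(max_excluded + 1):
        subset = cohort[cohort["ue_bin"] > k]
        row: dict = {"k": k, "n_retained": int(len(subset))}
        for adjusted, tag in ((False, "unadjusted"), (True, "adjusted")):
            try:
                est = fit_diet_effect(subset, adjusted, config, per_protocol)
                if k == 0:
                    base[adjusted] = est
                row[f"estimate_{tag}"] = est.estimate
                row[f"se_{tag}"] = est.se
                row[f"p_{tag}"] = est.p_value
                if adjusted in base and base[adjusted].estimate != 0:
                    row[f"attenuation_{tag}"] = 1.0 - est.estimate / base[adjusted].estimate
                else:
                    row[f"attenuation_{tag}"] = np.nan
            except ValueError as exc:
                row[f"estimate_{tag}"] = np.nan
                row[f"se_{tag}"] = np.nan
                row[f"p_{tag}"] = np.nan
                row[f"attenuation_{tag}"] = np.nan
                row[f"undefined_{tag}"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(table=table, max_excluded=max_excluded, per_protocol=per_protocol)


def compare_extreme_groups(
    cohort: pd.DataFrame, config: ScenarioConfig
) -> dict:
    """Adjusted diet effect in the low- vs high-UE halves and the p-value
    of the UE-group-by-diet interaction."""
    low, high, p_inter = fit_group_interaction(cohort, config)
    return {
        "low_ue": low,
        "high_ue": high,
        "p_interaction": p_inter,
    }
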