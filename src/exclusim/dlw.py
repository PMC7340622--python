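"""Doubly-labeled-water energetics.

The DLW method estimates CO2 production from isotope elimination and
converts it to energy expenditure with the abbreviated Weir equation,

    TEE = rCO2 * (k_O2 / RQ + k_CO2),      k_O2 = 3.941, k_CO2 = 1.106 kcal/L,

which requires an *assumed* respiratory quotient.  In feeding studies the
assumed RQ is the food quotient (FQ) of the prescribed diet - the
energy-weighted mean of the fuel RQs (carbohydrate 1.000, fat 0.710,
protein 0.835).  If a participant actually eats a different diet, their true
RQ diverges from the assumed one and measured TEE is biased by the ratio

    apparent TEE / true TEE = (k_O2/RQ_assumed + k_CO2) / (k_O2/RQ_true + k_CO2).

These three closed forms are the whole module; isotope kinetics (dilution
spaces, elimination rates) are upstream of rCO2 and out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DietComposition

__all__ = [
    "RQContext",
    "weir_energy_expenditure",
    "food_quotient",
    "rq_bias_ratio",
]

WEIR_O2 = 3.941  # kcal per liter O2
WEIR_CO2 = 1.106  # kcal per liter CO2
FUEL_RQ = {"carb": 1.000, "fat": 0.710, "protein": 0.835}

_RQ_RANGE = (0.6, 1.1)


def _check_rq(rq, name: str) -> None:
    rq = np.asarray(rq, dtype=float)
    if np.any(rq <= 0):
        raise ValueError(f"{name} must be positive, got {rq}")
    if np.any((rq < _RQ_RANGE[0]) | (rq > _RQ_RANGE[1])):
        raise ValueError(
            f"{name}={rq} outside the physiological range {_RQ_RANGE}"
        )


@dataclass(frozen=True)
class RQContext:
    """Assumed vs true respiratory quotient with Weir coefficients."""

    rq_assumed: float
    rq_true: float
    weir_o2: float = WEIR_O2
    weir_co2: float = WEIR_CO2

    def __post_init__(self) -> None:
        _check_rq(self.rq_assumed, "rq_assumed")
        _check_rq(self.rq_true, "rq_true")
        if self.weir_o2 <= 0 or self.weir_co2 <= 0:
            raise ValueError("Weir coefficients must be positive")


def weir_energy_expenditure(
    vco2, rq, weir_o2: float = WEIR_O2, weir_co2: float = WEIR_CO2
):
    """Energy expenditure (kcal/d) from CO2 production (L/d) at a given RQ."""
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vco2 <= 0):
        raise ValueError("vco2 must be positive")
    _check_rq(rq, "rq")
    out = vco2 * (weir_o2 / np.asarray(rq, dtype=float) + weir_co2)
    return out if out.ndim else float(out)


def food_quotient(
    diet: DietComposition,
    rq_carb: float = FUEL_RQ["carb"],
    rq_fat: float = FUEL_RQ["fat"],
    rq_protein: float = FUEL_RQ["protein"],
) -> float:
    """Food quotient: energy-fraction-weighted mean of the fuel RQs."""
    return (
        diet.carb_fraction * rq_carb
        + diet.fat_fraction * rq_fat
        + diet.protein_fraction * rq_protein
    )


def rq_bias_ratio(ctx: RQContext):
    """Multiplicative bias of DLW expenditure when the assumed RQ is wrong.

    Returns apparent/true TEE; equal RQs give exactly 1, and the ratio is
    strictly increasing in the true RQ at fixed assumed RQ.
    """
    num = ctx.weir_o2 / ctx.rq_assumed + ctx.weir_co2
    den = ctx.weir_o2 / ctx.rq_true + ctx.weir_co2
    return num / den
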