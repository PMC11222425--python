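"""Geochemical conversions and carbon/electron accounting for soil microcosms.

Raw bottle-level quantities (headspace pressure, gas composition, pH) are
converted to absolute amounts with the ideal gas law, sulfide is summed over
gas and dissolved pools via Henry's-law + first-dissociation speciation, and
amounts are normalised to mmole per gram dry soil. Cumulative amounts are then
aggregated as carbon molarity (amount x carbon atoms) and electron molarity
(amount x available electron equivalents), the two currencies used to compare
how treatments redirect fermented carbon and reducing power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .reaction_network import Metabolite, default_metabolites

__all__ = [
    "BottleState",
    "headspace_mmol",
    "total_h2s_mmol",
    "per_gram_dry_soil",
    "carbon_molarity",
    "electron_molarity",
    "change_summary",
    "effect_interaction",
    "DEFAULT_GROUPS",
]

R_GAS = 8.314  # L kPa mol^-1 K^-1

#: dimensionless aqueous/gas Henry solubility of H2S at 30 degC
H2S_HENRY_CC_30C = 2.45
#: first acid-dissociation constant of H2S at 30 degC
H2S_PKA1_30C = 6.98

#: fraction of slurry mass that is dry soil (endpoint gravimetry)
DEFAULT_DRY_FRACTION = 0.229

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "organic_acids": ("acetate", "lactate", "butyrate"),
    "co2": ("co2",),
    "ch4": ("ch4",),
}


@dataclass
class BottleState:
    """Physical state of one microcosm bottle at sampling."""

    headspace_pressure: float  # kPa
    headspace_volume: float  # L
    temperature: float  # K
    liquid_volume: float  # L
    pH: float
    gas_mole_fractions: Mapping[str, float] = field(default_factory=dict)
    slurry_mass: float = 40.0  # g
    dry_fraction: float = DEFAULT_DRY_FRACTION

    def __post_init__(self) -> None:
        for name, val in (
            ("headspace_pressure", self.headspace_pressure),
            ("headspace_volume", self.headspace_volume),
            ("temperature", self.temperature),
            ("liquid_volume", self.liquid_volume),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        fracs = dict(self.gas_mole_fractions)
        if any(not 0 <= x <= 1 for x in fracs.values()) or sum(fracs.values()) > 1 + 1e-9:
            raise ValueError("gas mole fractions must lie in [0,1] and sum to <= 1")
        if not 0 < self.dry_fraction < 1:
            raise ValueError("dry_fraction must be in (0,1)")


def headspace_mmol(state: BottleState, gas: str) -> float:
    """Moles of a headspace gas from the ideal gas law, in mmole.

    n = x_gas * P * V / (R * T).
    """
    if gas not in state.gas_mole_fractions:
        raise KeyError(f"gas {gas!r} not in bottle mole fractions")
    x = state.gas_mole_fractions[gas]
    n_mol = x * state.headspace_pressure * state.headspace_volume / (R_GAS * state.temperature)
    return 1000.0 * n_mol


def total_h2s_mmol(
    state: BottleState,
    gas_phase_h2s_mmol: float,
    henry_cc: float = H2S_HENRY_CC_30C,
    pka1: float = H2S_PKA1_30C,
) -> float:
    """Total sulfide (gas + dissolved H2S + HS-) from the gas-phase amount.

    The dissolved pool is the gas-phase concentration scaled by the
    dimensionless Henry solubility and the liquid volume, multiplied by
    (1 + 10^(pH - pKa1)) to include the deprotonated HS- fraction. The second
    dissociation (pKa2 >> slurry pH) is neglected. Monotone increasing in pH.
    """
    if not 0 <= state.pH <= 14:
        raise ValueError(f"pH must be in [0, 14], got {state.pH}")
    gas_conc = gas_phase_h2s_mmol / state.headspace_volume  # mmole/L
    dissolved = gas_conc * henry_cc * state.liquid_volume * (1.0 + 10.0 ** (state.pH - pka1))
    return gas_phase_h2s_mmol + dissolved


def per_gram_dry_soil(
    amount_mmol: float, slurry_mass_g: float, dry_fraction: float = DEFAULT_DRY_FRACTION
) -> float:
    """Normalise an absolute amount to mmole per gram dry soil."""
    if slurry_mass_g <= 0 or dry_fraction <= 0:
        raise ValueError("slurry mass and dry fraction must be positive")
    return amount_mmol / (slurry_mass_g * dry_fraction)


def _metabolite_map(metabolites: list[Metabolite] | None) -> dict[str, Metabolite]:
    return {m.id: m for m in (metabolites or default_metabolites())}


def carbon_molarity(
    amounts: Mapping[str, float],
    groups: Mapping[str, tuple[str, ...]] | None = None,
    metabolites: list[Metabolite] | None = None,
) -> dict[str, float]:
    """Carbon molarity (C-mmole/g dry soil) of named metabolite groups.

    Each group's value is the sum of amount x carbon atoms per molecule over
    its members; members absent from ``amounts`` contribute zero.
    """
    mets = _metabolite_map(metabolites)
    groups = dict(groups) if groups is not None else DEFAULT_GROUPS
    out: dict[str, float] = {}
    for gname, members in groups.items():
        total = 0.0
        for m in members:
            if m not in mets:
                raise KeyError(f"unknown metabolite {m!r} in group {gname!r}")
            total += amounts.get(m, 0.0) * mets[m].n_carbon
        out[gname] = total
    return out


def electron_molarity(
    amounts: Mapping[str, float],
    groups: Mapping[str, tuple[str, ...]] | None = None,
    metabolites: list[Metabolite] | None = None,
) -> dict[str, float]:
    """Electron molarity (e-mmole/g dry soil) of named metabolite groups.

    Uses available electron equivalents per mole (glucose 24, acetate 8,
    CH4 8, H2 2, H2S 8 as electrons accepted per sulfate reduced, ...).
    """
    mets = _metabolite_map(metabolites)
    groups = dict(groups) if groups is not None else DEFAULT_GROUPS
    out: dict[str, float] = {}
    for gname, members in groups.items():
        total = 0.0
        for m in members:
            if m not in mets:
                raise KeyError(f"unknown metabolite {m!r} in group {gname!r}")
            total += amounts.get(m, 0.0) * mets[m].e_equiv
        out[gname] = total
    return out


def change_summary(baseline: float, treated: float) -> dict:
    """Percent change and fold change of a treated value against a baseline.

    percent_change keeps its sign; fold_change is max/min with a direction
    flag, matching how treatment effects are conventionally reported.
    """
    if baseline == 0:
        return {
            "percent_change": None,
            "fold_change": None,
            "direction": None,
            "undefined_baseline": True,
        }
    pct = (treated - baseline) / baseline * 100.0
    if treated == baseline:
        fold, direction = 1.0, "unchanged"
    elif abs(treated) > abs(baseline):
        fold, direction = abs(treated / baseline), "increase"
    else:
        fold, direction = abs(baseline / treated) if treated != 0 else math.inf, "decrease"
    return {
        "percent_change": pct,
        "fold_change": fold,
        "direction": direction,
        "undefined_baseline": False,
    }


def effect_interaction(
    delta_a: float, delta_b: float, delta_ab: float, tol: float = 0.0
) -> str:
    """Classify a two-stressor interaction from single and combined effects.

    The combined effect is synergistic when its magnitude exceeds that of the
    summed single effects (beyond ``tol``), antagonistic when smaller, and
    additive within tolerance.
    """
    diff = abs(delta_ab) - abs(delta_a + delta_b)
    if diff > tol:
        return "synergistic"
    if diff < -tol:
        return "antagonistic"
    return "additive"
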