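"""Synthetic microcosm measurements and proteomes for closed-loop testing.

The generator emulates the statistical structure the analysis assumes: each
condition has a true vector of reaction extents; cumulative metabolite
amounts at each sampling day are the stoichiometric prediction scaled by a
shared monotone activity profile plus truncated Gaussian replicate noise; and
proteomes are log-normal protein abundances with multiplicative guild-by-
condition effects, with a configurable fraction of proteins shared between
two species to exercise the equal-split rollup rule.

Defaults mirror the study design: four redox conditions, sampling on days
2/9/16/23/30 with three replicate bottles each, true fluxes at the magnitudes
fitted from the endpoint measurements, and replicate noise at the scale of
the reported endpoint standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .proteome_summary import GUILDS, ProteinRecord
from .reaction_network import CONDITIONS, ReactionNetwork, active_network, condition_flags

__all__ = [
    "SimulationConfig",
    "simulate_measurements",
    "simulate_proteome",
    "DEFAULT_TRUE_FLUXES",
    "DEFAULT_NOISE_SD",
    "DEFAULT_ACTIVITY_PROFILE",
]

SAMPLING_DAYS = (2, 9, 16, 23, 30)

#: true reaction extents per condition (mmole reference species / g dry soil),
#: at the magnitudes estimated from the endpoint measurements
DEFAULT_TRUE_FLUXES: dict[str, dict[str, float]] = {
    "S-O-": {
        "lactate_fermentation": 0.005,
        "hydrogenic_acetogenesis": 0.14,
        "hydrogenotrophic_methanogenesis": 0.14,
        "acetoclastic_methanogenesis": 0.18,
        "butyrate_production": 0.045,
    },
    "S+O-": {
        "lactate_fermentation": 0.018,
        "hydrogenic_acetogenesis": 0.16,
        "sulfidogenic_h2_oxidation": 0.16,
        "acetoclastic_methanogenesis": 0.099,
        "butyrate_production": 0.032,
    },
    "S-O+": {
        "aerobic_heterotrophy": 0.12,
        "lactate_fermentation": 0.006,
        "hydrogenic_acetogenesis": 0.014,
        "hydrogenotrophic_methanogenesis": 0.003,
        "acetoclastic_methanogenesis": 0.006,
    },
    "S+O+": {
        "aerobic_heterotrophy": 0.13,
        "lactate_fermentation": 0.0095,
        "hydrogenic_acetogenesis": 0.011,
        "sulfidogenic_lactate_oxidation": 0.003,
        "hydrogenotrophic_methanogenesis": 0.002,
        "acetoclastic_methanogenesis": 0.006,
    },
}

#: replicate noise SD per fitted metabolite (mmole/g), endpoint-report scale
DEFAULT_NOISE_SD: dict[str, float] = {
    "acetate": 0.012,
    "lactate": 0.002,
    "butyrate": 0.002,
    "h2": 0.005,
    "co2": 0.02,
    "ch4": 0.007,
    "h2s": 0.008,
}

#: fraction of total incubation activity realised by each sampling day;
#: fast early fermentation then saturation, anchored at 1 on the final day
DEFAULT_ACTIVITY_PROFILE: dict[float, float] = {2: 0.1, 9: 0.4, 16: 0.65, 23: 0.85, 30: 1.0}


@dataclass
class SimulationConfig:
    """Parameters of a microcosm simulation."""

    true_fluxes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_TRUE_FLUXES.items()}
    )
    activity_profile: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_PROFILE)
    )
    noise_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    n_replicates: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        days = sorted(self.activity_profile)
        fracs = [self.activity_profile[d] for d in days]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("activity profile must be monotone nondecreasing")
        if fracs and fracs[-1] != 1.0:
            raise ValueError("activity profile must reach 1 on the final day")
        if any(s < 0 for s in self.noise_sd.values()):
            raise ValueError("noise SDs must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for v in self.true_fluxes.values():
            if any(x < 0 for x in v.values()):
                raise ValueError("true fluxes must be nonnegative")


def simulate_measurements(net: ReactionNetwork, cfg: SimulationConfig) -> pd.DataFrame:
    """Simulate a long-format cumulative measurement table.

    For condition c, replicate k, day t and fitted metabolite m the amount is
    ``f(t) * (S v_c)_m + eps`` with ``eps ~ Normal(0, noise_sd[m])``,
    truncated at zero wherever the noiseless cumulative production is
    nonnegative. Raises if a condition's fluxes include a reaction excluded
    by its oxygen/sulfate flags. Reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for cond in cfg.true_fluxes:
        sulfate, oxic = condition_flags(cond)
        sub = active_network(net, oxic=oxic, sulfate_added=sulfate)
        extra = set(cfg.true_fluxes[cond]) - set(sub.reaction_ids)
        if extra:
            raise ValueError(
                f"{cond}: flux assigned to reaction(s) inactive under this condition: {sorted(extra)}"
            )
        v = np.array([cfg.true_fluxes[cond].get(r, 0.0) for r in sub.reaction_ids])
        endpoint = sub.fitted_matrix() @ v
        for day in sorted(cfg.activity_profile):
            frac = cfg.activity_profile[day]
            for rep in range(1, cfg.n_replicates + 1):
                for m, clean in zip(sub.fitted_species, endpoint):
                    val = frac * clean + rng.normal(0.0, cfg.noise_sd.get(m, 0.0))
                    if clean >= 0:
                        val = max(val, 0.0)
                    rows.append(
                        {
                            "condition": cond,
                            "replicate": rep,
                            "day": day,
                            "metabolite_id": m,
                            "amount_mmol_per_g_dry_soil": val,
                        }
                    )
    return pd.DataFrame(rows)


#: guild proteome multiplier per condition, shaped after the observed guild
#: shifts (methanogens dominant anoxic without sulfate, SRB enriched by
#: sulfate, methanotrophs/SOB enriched by oxygen)
DEFAULT_GUILD_PROFILES: dict[str, dict[str, float]] = {
    "methanogen": {"S-O-": 1.0, "S+O-": 0.55, "S-O+": 0.25, "S+O+": 0.2},
    "methanotroph": {"S-O-": 0.2, "S+O-": 0.3, "S-O+": 1.0, "S+O+": 1.2},
    "SRB": {"S-O-": 0.4, "S+O-": 1.0, "S-O+": 0.3, "S+O+": 0.6},
    "SOB": {"S-O-": 0.2, "S+O-": 0.4, "S-O+": 0.8, "S+O+": 1.0},
    "polymer_degrader": {"S-O-": 1.0, "S+O-": 0.8, "S-O+": 0.6, "S+O+": 0.5},
    "other": {c: 1.0 for c in CONDITIONS},
}


def simulate_proteome(
    guild_profiles: Mapping[str, Mapping[str, float]] | None = None,
    n_species: int = 40,
    n_proteins: int = 400,
    seed: int = 42,
    n_replicates: int = 3,
    shared_fraction: float = 0.1,
    lognormal_sigma: float = 0.6,
    replicate_cv: float = 0.15,
) -> list[ProteinRecord]:
    """Simulate a guild-structured protein abundance table.

    Species are assigned round-robin to guilds; each protein belongs to one
    species (or two, for a ``shared_fraction`` of proteins, exercising the
    equal-split rollup). Base abundances are log-normal; each sample
    ``<condition>_r<k>`` scales a protein by its guild's condition multiplier
    and log-normal replicate noise of coefficient of variation
    ``replicate_cv``. Reproducible from ``seed``.
    """
    profiles = {g: dict(v) for g, v in (guild_profiles or DEFAULT_GUILD_PROFILES).items()}
    for g, prof in profiles.items():
        if any(x < 0 for x in prof.values()):
            raise ValueError(f"negative condition multiplier for guild {g!r}")
    rng = np.random.default_rng(seed)
    guilds = [g for g in GUILDS if g in profiles]
    species_guild = {f"sp{(i + 1):03d}": guilds[i % len(guilds)] for i in range(n_species)}
    species_ids = list(species_guild)

    records = []
    for i in range(n_proteins):
        primary = species_ids[int(rng.integers(n_species))]
        owners = [primary]
        if rng.random() < shared_fraction:
            # share with another species of the same guild where possible
            mates = [s for s in species_ids if s != primary and species_guild[s] == species_guild[primary]]
            pool = mates or [s for s in species_ids if s != primary]
            owners.append(pool[int(rng.integers(len(pool)))])
        guild = species_guild[primary]
        base = float(rng.lognormal(mean=0.0, sigma=lognormal_sigma))
        abundance = {}
        for cond in CONDITIONS:
            mult = profiles[guild].get(cond, 1.0)
            for rep in range(1, n_replicates + 1):
                noise = float(rng.lognormal(mean=0.0, sigma=replicate_cv))
                abundance[f"{cond}_r{rep}"] = base * mult * noise
        records.append(
            ProteinRecord(
                protein_id=f"prot{(i + 1):04d}",
                species_ids=tuple(owners),
                abundance=abundance,
                guild=guild,
            )
        )
    return records
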