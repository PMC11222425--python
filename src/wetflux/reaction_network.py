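"""Guild-level reaction network for anaerobic/aerobic wetland soil food webs.

The network describes the overall (lumped) metabolism of the major functional
guilds in a wetland soil community: polysaccharide-derived glucose is fermented
to organic acids, H2 and CO2; sulfate reducers oxidise lactate or H2 against
SO4^2-; methanogens produce CH4 from H2/CO2 or acetate; and, when oxygen is
present, aerobic heterotrophs and methanotrophs respire substrates to CO2.
Each reaction is written per mole of a designated reference species, with
exact rational stoichiometric coefficients, and must balance both carbon and
available electrons (degree of reduction).

Electron bookkeeping convention
-------------------------------
Every metabolite carries an integer number of available electron equivalents
per mole (24 for glucose, 8 for acetate, ...). Sulfide is assigned 8 e-/mole:
the electrons accepted per sulfate reduced to sulfide, so sulfate itself
enters the balance at zero. O2 is a pure acceptor contributing 4 e-/mole
consumed. A reaction balances when donated electrons equal the electrons in
products plus those taken up by O2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "ReactionNetwork",
    "default_metabolites",
    "default_network",
    "active_network",
    "read_network",
    "write_network",
]

#: electrons accepted per mole of O2 reduced to water
O2_ELECTRON_ACCEPTANCE = 4

#: the seven species whose cumulative amounts the flux fit targets
DEFAULT_FITTED_SPECIES = ("acetate", "lactate", "butyrate", "h2", "co2", "ch4", "h2s")

CONDITIONS = ("S-O-", "S+O-", "S-O+", "S+O+")


def condition_flags(condition: str) -> tuple[bool, bool]:
    """Map a condition label like ``'S+O-'`` to (sulfate_added, oxic)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return condition[1] == "+", condition[3] == "+"


@dataclass(frozen=True)
class Metabolite:
    """A chemical species tracked by the network.

    Parameters
    ----------
    id : short key used in stoichiometry maps and measurement tables.
    name : human-readable label.
    n_carbon : carbon atoms per molecule.
    e_equiv : available electron equivalents per mole (degree of reduction);
        for sulfide this is the 8 e- accepted per sulfate reduced.
    role : ``"fitted"`` species enter the least-squares objective;
        ``"substrate"`` (glucose) and ``"acceptor"`` (O2, SO4) do not.
    """

    id: str
    name: str
    n_carbon: int
    e_equiv: int
    role: str = "fitted"

    def __post_init__(self) -> None:
        if self.n_carbon < 0 or self.e_equiv < 0:
            raise ValueError(f"negative carbon/electron content for {self.id}")
        if self.role not in ("fitted", "substrate", "acceptor"):
            raise ValueError(f"unknown role {self.role!r} for {self.id}")


@dataclass(frozen=True)
class Reaction:
    """A guild-level overall transformation.

    ``stoichiometry`` maps metabolite id to a signed exact coefficient per
    unit reaction extent (negative = consumed). ``reference_species`` is the
    metabolite whose coefficient has magnitude one; fluxes are reported in
    mmole of that species per g dry soil.
    """

    id: str
    name: str
    stoichiometry: Mapping[str, Fraction]
    reference_species: str
    requires_oxygen: bool = False
    requires_sulfate: bool = False

    def __post_init__(self) -> None:
        stoich = {k: Fraction(v) for k, v in self.stoichiometry.items()}
        object.__setattr__(self, "stoichiometry", stoich)
        ref = stoich.get(self.reference_species)
        if ref is None or abs(ref) != 1:
            raise ValueError(
                f"{self.id}: reference species {self.reference_species!r} must carry "
                f"coefficient +/-1, got {ref}"
            )

    def carbon_residual(self, metabolites: Mapping[str, Metabolite]) -> Fraction:
        return sum(
            (c * metabolites[m].n_carbon for m, c in self.stoichiometry.items()),
            Fraction(0),
        )

    def electron_residual(self, metabolites: Mapping[str, Metabolite]) -> Fraction:
        total = Fraction(0)
        for m, c in self.stoichiometry.items():
            met = metabolites[m]
            total += c * met.e_equiv
            if met.id == "o2":
                # O2 is consumed (c < 0) and accepts 4 e-/mole
                total += -c * O2_ELECTRON_ACCEPTANCE
        return total


@dataclass
class ReactionNetwork:
    """An ordered set of metabolites and reactions with its stoichiometric matrix."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    fitted_species: tuple[str, ...] = DEFAULT_FITTED_SPECIES
    S: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ValueError("duplicate metabolite ids")
        index = {m: i for i, m in enumerate(met_ids)}
        missing = [
            m
            for r in self.reactions
            for m in r.stoichiometry
            if m not in index
        ]
        if missing:
            raise ValueError(f"reactions reference undeclared metabolites: {sorted(set(missing))}")
        S = np.zeros((len(met_ids), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for m, c in r.stoichiometry.items():
                S[index[m], j] = float(c)
        self.S = S
        self.validate()

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def validate(self) -> None:
        """Assert exact carbon and electron balance of every reaction."""
        mets = {m.id: m for m in self.metabolites}
        for r in self.reactions:
            c_res = r.carbon_residual(mets)
            if c_res != 0:
                raise ValueError(f"{r.id}: carbon imbalance {c_res}")
            e_res = r.electron_residual(mets)
            if e_res != 0:
                raise ValueError(f"{r.id}: electron imbalance {e_res}")

    def fitted_matrix(self) -> np.ndarray:
        """S restricted to the fitted species (rows ordered as fitted_species)."""
        index = {m: i for i, m in enumerate(self.metabolite_ids)}
        rows = [index[m] for m in self.fitted_species]
        return self.S[rows, :]

    def network_hash(self) -> str:
        """Stable hex digest of the network definition, for report provenance."""
        import hashlib

        parts = []
        for m in self.metabolites:
            parts.append(f"{m.id}|{m.n_carbon}|{m.e_equiv}|{m.role}")
        for r in self.reactions:
            stoich = ";".join(f"{k}:{v}" for k, v in sorted(r.stoichiometry.items()))
            parts.append(
                f"{r.id}|{stoich}|{r.reference_species}|{int(r.requires_oxygen)}|{int(r.requires_sulfate)}"
            )
        return hashlib.sha256("\n".join(parts).encode()).hexdigest()[:16]


def default_metabolites() -> list[Metabolite]:
    """The study's metabolite set with carbon and electron content per mole."""
    return [
        Metabolite("glucose", "glucose", 6, 24, role="substrate"),
        Metabolite("acetate", "acetate", 2, 8),
        Metabolite("lactate", "lactate", 3, 12),
        Metabolite("butyrate", "butyrate", 4, 20),
        Metabolite("h2", "hydrogen", 0, 2),
        Metabolite("co2", "carbon dioxide", 1, 0),
        Metabolite("ch4", "methane", 1, 8),
        Metabolite("h2s", "hydrogen sulfide", 0, 8),
        Metabolite("o2", "oxygen", 0, 0, role="acceptor"),
        Metabolite("so4", "sulfate", 0, 0, role="acceptor"),
    ]


def _rxn(
    rid: str,
    name: str,
    stoich: dict[str, int | str | Fraction],
    ref: str,
    o2: bool = False,
    so4: bool = False,
) -> Reaction:
    return Reaction(
        rid,
        name,
        {k: Fraction(v) for k, v in stoich.items()},
        reference_species=ref,
        requires_oxygen=o2,
        requires_sulfate=so4,
    )


def default_network() -> ReactionNetwork:
    """The nine guild-level overall reactions fit to the microcosm data.

    Each reaction is normalised to one mole of its reference species
    (glucose for the fermentations and aerobic heterotrophy, sulfate for
    the sulfidogenic oxidations, methane for the methanogenic and
    methanotrophic reactions).
    """
    reactions = [
        _rxn(
            "aerobic_heterotrophy",
            "aerobic heterotrophy",
            {"glucose": -1, "o2": -6, "co2": 6},
            "glucose",
            o2=True,
        ),
        _rxn(
            "lactate_fermentation",
            "lactate fermentation",
            {"glucose": -1, "lactate": 2},
            "glucose",
        ),
        _rxn(
            "hydrogenic_acetogenesis",
            "hydrogenic acetogenesis",
            {"glucose": -1, "acetate": 2, "co2": 2, "h2": 4},
            "glucose",
        ),
        _rxn(
            "sulfidogenic_lactate_oxidation",
            "sulfidogenic lactate oxidation",
            {"lactate": -2, "so4": -1, "acetate": 2, "co2": 2, "h2s": 1},
            "so4",
            so4=True,
        ),
        _rxn(
            "sulfidogenic_h2_oxidation",
            "sulfidogenic hydrogen oxidation",
            {"h2": -4, "so4": -1, "h2s": 1},
            "so4",
            so4=True,
        ),
        _rxn(
            "hydrogenotrophic_methanogenesis",
            "hydrogenotrophic methanogenesis",
            {"h2": -4, "co2": -1, "ch4": 1},
            "ch4",
        ),
        _rxn(
            "acetoclastic_methanogenesis",
            "acetoclastic methanogenesis",
            {"acetate": -1, "ch4": 1, "co2": 1},
            "ch4",
        ),
        _rxn(
            "methane_oxidation",
            "methane oxidation",
            {"ch4": -1, "o2": -2, "co2": 1},
            "ch4",
            o2=True,
        ),
        _rxn(
            "butyrate_production",
            "butyrate production",
            {"glucose": -1, "butyrate": 1, "co2": 2, "h2": 2},
            "glucose",
        ),
    ]
    return ReactionNetwork(default_metabolites(), reactions)


def active_network(
    net: ReactionNetwork, oxic: bool, sulfate_added: bool
) -> ReactionNetwork:
    """Subnetwork of reactions whose electron-acceptor requirements are met.

    Oxygen-requiring reactions are retained only under oxic incubation and
    sulfate-requiring ones only when sulfate was added; all other reactions
    are always retained — the non-negative fit, not masking, drives inactive
    fluxes toward zero.
    """
    keep = [
        r
        for r in net.reactions
        if (oxic or not r.requires_oxygen) and (sulfate_added or not r.requires_sulfate)
    ]
    return ReactionNetwork(list(net.metabolites), keep, net.fitted_species)


# ---------------------------------------------------------------------------
# TSV round-trip


def write_network(net: ReactionNetwork, directory: str | Path) -> dict[str, Path]:
    """Write metabolite, reaction-metadata and stoichiometry TSVs.

    Coefficients are serialised as exact rationals (``-1``, ``1/2``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    met_path = directory / "metabolites.tsv"
    meta_path = directory / "reactions.tsv"
    stoich_path = directory / "stoichiometry.tsv"

    pd.DataFrame(
        [
            {
                "metabolite_id": m.id,
                "name": m.name,
                "n_carbon": m.n_carbon,
                "e_equiv": m.e_equiv,
                "role": m.role,
            }
            for m in net.metabolites
        ]
    ).to_csv(met_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "reaction_id": r.id,
                "name": r.name,
                "reference_species": r.reference_species,
                "requires_oxygen": r.requires_oxygen,
                "requires_sulfate": r.requires_sulfate,
            }
            for r in net.reactions
        ]
    ).to_csv(meta_path, sep="\t", index=False)
    rows = [
        {"reaction_id": r.id, "metabolite_id": m, "coefficient": str(c)}
        for r in net.reactions
        for m, c in r.stoichiometry.items()
    ]
    pd.DataFrame(rows).to_csv(stoich_path, sep="\t", index=False)
    return {"metabolites": met_path, "reactions": meta_path, "stoichiometry": stoich_path}


def read_network(directory: str | Path) -> ReactionNetwork:
    """Read a network from the three TSVs written by :func:`write_network`."""
    directory = Path(directory)
    mets_df = pd.read_csv(directory / "metabolites.tsv", sep="\t")
    meta_df = pd.read_csv(directory / "reactions.tsv", sep="\t")
    stoich_df = pd.read_csv(directory / "stoichiometry.tsv", sep="\t", dtype=str)

    metabolites = [
        Metabolite(
            str(row.metabolite_id),
            str(row.name),
            int(row.n_carbon),
            int(row.e_equiv),
            str(row.role),
        )
        for row in mets_df.itertuples()
    ]
    # U+2212 minus sometimes appears in hand-edited definition files
    coeffs: dict[str, dict[str, Fraction]] = {}
    for row in stoich_df.itertuples():
        coeffs.setdefault(str(row.reaction_id), {})[str(row.metabolite_id)] = Fraction(
            str(row.coefficient).replace("−", "-")
        )
    reactions = [
        Reaction(
            str(row.reaction_id),
            str(row.name),
            coeffs[str(row.reaction_id)],
            reference_species=str(row.reference_species),
            requires_oxygen=_parse_bool(row.requires_oxygen),
            requires_sulfate=_parse_bool(row.requires_sulfate),
        )
        for row in meta_df.itertuples()
    ]
    return ReactionNetwork(metabolites, reactions)


def _parse_bool(x: object) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("true", "1", "yes")
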