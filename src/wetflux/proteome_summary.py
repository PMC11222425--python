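"""Metaproteome rollups: species abundance, diversity, guild correlations.

Protein-level label-free abundances are rolled up to species (a protein
identified in several species has its abundance split equally among them),
species tables are summarised by richness and Pielou evenness, guild
abundances are correlated with geochemical endpoints (Pearson r, t-test p),
and a simplified differential-abundance procedure (log2 fold change, Welch t,
Benjamini-Hochberg q) flags proteins shifting between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteinRecord",
    "SpeciesAbundanceTable",
    "species_rollup",
    "diversity",
    "guild_correlation",
    "differential_abundance",
    "read_protein_table",
    "guild_abundance",
]

GUILDS = ("methanogen", "methanotroph", "SRB", "SOB", "polymer_degrader", "other")


@dataclass(frozen=True)
class ProteinRecord:
    """One quantified protein in one or more samples.

    ``abundance`` maps sample name -> nonnegative normalised intensity.
    ``species_ids`` lists every species the protein was identified in;
    protein groups (ambiguous inference) are excluded upstream.
    """

    protein_id: str
    species_ids: tuple[str, ...]
    abundance: Mapping[str, float]
    guild: str | None = None

    def __post_init__(self) -> None:
        if not self.species_ids:
            raise ValueError(f"{self.protein_id}: empty species list")
        if any(a < 0 for a in self.abundance.values()):
            raise ValueError(f"{self.protein_id}: negative abundance")
        if self.guild is not None and self.guild not in GUILDS:
            raise ValueError(f"{self.protein_id}: unknown guild {self.guild!r}")


@dataclass
class SpeciesAbundanceTable:
    """Sample x species abundance matrix with the split rule recorded."""

    table: pd.DataFrame  # index: sample, columns: species
    provenance: str = "shared proteins split equally among identified species"

    def relative(self) -> pd.DataFrame:
        totals = self.table.sum(axis=1)
        return self.table.div(totals.replace(0, np.nan), axis=0)


def species_rollup(records: Sequence[ProteinRecord]) -> SpeciesAbundanceTable:
    """Sum protein abundances per species, splitting shared proteins equally.

    Abundance is conserved exactly: per sample, the species totals sum to the
    total input protein abundance.
    """
    cells: dict[tuple[str, str], float] = {}
    samples: list[str] = []
    seen = set()
    for rec in records:
        share = 1.0 / len(rec.species_ids)
        for sample, a in rec.abundance.items():
            if sample not in seen:
                seen.add(sample)
                samples.append(sample)
            for sp in rec.species_ids:
                cells[(sample, sp)] = cells.get((sample, sp), 0.0) + a * share
    species = sorted({sp for (_, sp) in cells})
    mat = pd.DataFrame(0.0, index=samples, columns=species)
    for (sample, sp), val in cells.items():
        mat.loc[sample, sp] = val
    return SpeciesAbundanceTable(mat)


def diversity(table: SpeciesAbundanceTable, sample: str) -> dict:
    """Richness and Pielou evenness of one sample.

    Richness counts species with abundance > 0; evenness is Shannon entropy
    of relative abundances over ln(richness), undefined (None) when richness
    is 0 or 1.
    """
    row = table.table.loc[sample]
    present = row[row > 0]
    richness = int(present.size)
    if richness <= 1:
        return {"richness": richness, "evenness": None}
    p = (present / present.sum()).to_numpy()
    shannon = float(-(p * np.log(p)).sum())
    return {"richness": richness, "evenness": shannon / np.log(richness)}


def guild_correlation(
    guild_abundance: Sequence[float], endpoint: Sequence[float]
) -> dict:
    """Pearson correlation of a guild's proteome abundance with a gas endpoint.

    p comes from the t statistic r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom (two-sided). Requires >= 3 paired samples.
    """
    x = np.asarray(guild_abundance, dtype=float)
    y = np.asarray(endpoint, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return {"r": None, "p": None, "zero_variance": True}
    r, p = scipy.stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "zero_variance": False}


def differential_abundance(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    pseudo_scale: float = 1e-6,
) -> pd.DataFrame:
    """Per-protein log2 fold change with Welch t p-values and BH q-values.

    ``group_a``/``group_b``: protein x sample abundance frames sharing an
    index. A pseudo-abundance of ``pseudo_scale`` x the median nonzero
    abundance stabilises fold changes of zero entries. q < 0.05 is the
    conventional significance threshold. This is a simplified two-group
    procedure, not a negative-binomial GLM; the choice is recorded in the
    returned frame's ``attrs["method"]``.
    """
    if group_a.shape[1] < 2 or group_b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    if not group_a.index.equals(group_b.index):
        raise ValueError("groups must share a protein index")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    pooled = np.concatenate([a.ravel(), b.ravel()])
    nonzero = pooled[pooled > 0]
    eps = pseudo_scale * (np.median(nonzero) if nonzero.size else 1.0)
    log2fc = np.log2((a.mean(axis=1) + eps) / (b.mean(axis=1) + eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical rows
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"log2FC": log2fc, "p": p, "q": q, "significant": q < 0.05},
        index=group_a.index,
    )
    out.attrs["method"] = "log2 fold change + Welch t-test + Benjamini-Hochberg"
    return out


# ---------------------------------------------------------------------------
# I/O helpers


def read_protein_table(path: str | Path) -> list[ProteinRecord]:
    """Read a protein TSV: protein_id, species_ids (semicolon-separated),
    guild, then one abundance column per sample (e.g. ``S+O-_r2``)."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["protein_id", "species_ids", "guild"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise ValueError(f"protein table missing columns: {sorted(missing)}")
    sample_cols = [c for c in df.columns if c not in fixed]
    records = []
    for _, row in df.iterrows():  # sample names like "S+O-_r2" are not identifiers
        guild = row["guild"]
        guild = None if pd.isna(guild) or guild == "" else str(guild)
        records.append(
            ProteinRecord(
                protein_id=str(row["protein_id"]),
                species_ids=tuple(str(row["species_ids"]).split(";")),
                guild=guild,
                abundance={c: float(row[c]) for c in sample_cols},
            )
        )
    return records


def guild_abundance(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Total protein abundance per guild per sample (sample x guild frame)."""
    cells: dict[str, dict[str, float]] = {}
    for rec in records:
        g = rec.guild or "other"
        for sample, a in rec.abundance.items():
            cells.setdefault(sample, {}).setdefault(g, 0.0)
            cells[sample][g] += a
    return pd.DataFrame(cells).T.fillna(0.0).sort_index()
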