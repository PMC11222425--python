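"""End-to-end pipeline: endpoints -> flux fits -> partitions -> accounting.

``run_pipeline`` takes endpoint summaries (mean +/- SD per condition and
metabolite, either from the packaged endpoint fixture or summarised from a
long replicate table), fits the active reaction network per condition with
bootstrap uncertainty, partitions CO2/CH4 by reaction, compares fluxes
between conditions, and assembles carbon/electron molarity tables and
treatment-effect summaries into one JSON-serialisable report.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .flux_fit import (
    FluxEstimate,
    bootstrap_fluxes_from_moments,
    compare_fluxes,
    partition_gas,
)
from .geochem import change_summary, effect_interaction, electron_molarity, carbon_molarity
from .reaction_network import (
    CONDITIONS,
    ReactionNetwork,
    active_network,
    condition_flags,
    default_network,
)

__all__ = [
    "load_endpoints",
    "summarize_endpoint",
    "run_pipeline",
    "validate_report",
    "write_report",
]

BASELINE_CONDITION = "S-O-"

REPORT_REQUIRED_KEYS = (
    "conditions",
    "fits",
    "partitions",
    "change_summaries",
    "carbon_molarity",
    "electron_molarity",
    "interactions",
    "flux_tests",
    "provenance",
)


def load_endpoints() -> pd.DataFrame:
    """The packaged endpoint fixture: cumulative 30-day accumulations
    (mean +/- SD, mmole/g dry soil) of the measured metabolites under the
    four redox conditions."""
    ref = importlib.resources.files("wetflux.data") / "endpoint_accumulations.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def summarize_endpoint(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long replicate table to endpoint mean/SD per condition.

    The endpoint is each condition's last sampling day.
    """
    rows = []
    for cond, sub in measurements.groupby("condition"):
        endpoint = sub[sub["day"] == sub["day"].max()]
        g = endpoint.groupby("metabolite_id")["amount_mmol_per_g_dry_soil"]
        stats = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0)})
        for m, row in stats.iterrows():
            rows.append(
                {
                    "condition": cond,
                    "metabolite_id": m,
                    "mean_mmol_per_g_dry_soil": row["mean"],
                    "sd_mmol_per_g_dry_soil": row["sd"],
                }
            )
    return pd.DataFrame(rows)


def _condition_moments(
    summary: pd.DataFrame, condition: str
) -> tuple[dict[str, float], dict[str, float]]:
    sub = summary[summary["condition"] == condition]
    means = dict(zip(sub["metabolite_id"], sub["mean_mmol_per_g_dry_soil"]))
    sds = dict(zip(sub["metabolite_id"], sub["sd_mmol_per_g_dry_soil"]))
    return means, sds


def run_pipeline(
    summary: pd.DataFrame,
    net: ReactionNetwork | None = None,
    n_boot: int = 1000,
    seed: int = 42,
    compare_reactions: tuple[str, ...] | None = None,
) -> dict:
    """Run the full stoichiometric analysis and return the report dict.

    Parameters
    ----------
    summary : endpoint table with columns condition, metabolite_id,
        mean_mmol_per_g_dry_soil, sd_mmol_per_g_dry_soil (see
        :func:`load_endpoints` / :func:`summarize_endpoint`).
    net : reaction network; the default nine-reaction network if None.
    n_boot, seed : parametric-bootstrap settings, echoed into provenance.
    compare_reactions : reactions tested (each treatment vs the anoxic
        non-sulfate baseline) with Wald chi-square; defaults to the union of
        reactions active anywhere.

    Deterministic for fixed inputs and seed.
    """
    if summary.empty:
        raise ValueError("empty measurement summary")
    net = net or default_network()
    conditions = [c for c in CONDITIONS if c in set(summary["condition"])]
    if not conditions:
        raise ValueError("no recognised conditions in measurement summary")

    fits: dict[str, FluxEstimate] = {}
    partitions = {}
    gaps = []
    for i, cond in enumerate(conditions):
        sulfate, oxic = condition_flags(cond)
        sub = active_network(net, oxic=oxic, sulfate_added=sulfate)
        means, sds = _condition_moments(summary, cond)
        missing = [m for m in sub.fitted_species if m not in means]
        if missing:
            gaps.append({"condition": cond, "missing_metabolites": missing})
            continue
        est = bootstrap_fluxes_from_moments(
            sub, means, sds, n_boot=n_boot, seed=seed + i, condition=cond
        )
        fits[cond] = est
        partitions[cond] = partition_gas(sub, est)

    # treatment effects on endpoint accumulations, relative to the baseline
    change, interactions = {}, {}
    molar_c, molar_e = {}, {}
    e_groups = {
        "organic_acids": ("acetate", "lactate", "butyrate"),
        "h2": ("h2",),
        "ch4": ("ch4",),
        "h2s": ("h2s",),
    }
    amounts_by_cond = {}
    for cond in conditions:
        means, _ = _condition_moments(summary, cond)
        known = {m: v for m, v in means.items() if m in {mm.id for mm in net.metabolites}}
        amounts_by_cond[cond] = known
        molar_c[cond] = carbon_molarity(known, metabolites=net.metabolites)
        molar_e[cond] = electron_molarity(known, e_groups, metabolites=net.metabolites)

    if BASELINE_CONDITION in amounts_by_cond:
        base = amounts_by_cond[BASELINE_CONDITION]
        base_e = molar_e[BASELINE_CONDITION]
        for cond in conditions:
            if cond == BASELINE_CONDITION:
                continue
            change[cond] = {
                "ch4": change_summary(base.get("ch4", 0.0), amounts_by_cond[cond].get("ch4", 0.0)),
                "co2": change_summary(base.get("co2", 0.0), amounts_by_cond[cond].get("co2", 0.0)),
                "electrons_to_h2": change_summary(
                    base_e["h2"], molar_e[cond]["h2"]
                ),
            }
        if all(c in amounts_by_cond for c in CONDITIONS):
            for gas in ("ch4", "co2"):
                deltas = [
                    change[c][gas]["percent_change"] for c in ("S+O-", "S-O+", "S+O+")
                ]
                if None not in deltas:
                    interactions[gas] = effect_interaction(deltas[0], deltas[1], deltas[2])

    # Wald comparisons of each treatment against the baseline
    tests = {}
    if BASELINE_CONDITION in fits:
        rxn_ids = compare_reactions or tuple(net.reaction_ids)
        for cond in conditions:
            if cond == BASELINE_CONDITION or cond not in fits:
                continue
            shared = [
                r
                for r in rxn_ids
                if r in fits[cond].flux and r in fits[BASELINE_CONDITION].flux
            ]
            tests[cond] = [
                {
                    "reaction_id": res.reaction_id,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p,
                    "q": res.q,
                    "degenerate_variance": res.degenerate_variance,
                }
                for res in compare_fluxes(fits[BASELINE_CONDITION], fits[cond], shared)
            ]

    report = {
        "conditions": conditions,
        "fits": {c: est.as_dict() for c, est in fits.items()},
        "partitions": {c: p.as_dict() for c, p in partitions.items()},
        "change_summaries": change,
        "carbon_molarity": molar_c,
        "electron_molarity": molar_e,
        "interactions": interactions,
        "flux_tests": tests,
        "gaps": gaps,
        "provenance": {
            "seed": seed,
            "n_boot": n_boot,
            "network_hash": net.network_hash(),
            "baseline_condition": BASELINE_CONDITION,
            "software_version": __version__,
        },
    }
    validate_report(report)
    return report


def validate_report(report: Mapping) -> None:
    """Check the report carries every required section."""
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise ValueError(f"report missing sections: {missing}")
    for cond in report["fits"]:
        fit = report["fits"][cond]
        if not all(k in fit for k in ("flux", "flux_sd", "residuals", "r_squared", "seed")):
            raise ValueError(f"incomplete fit record for {cond}")


def write_report(report: Mapping, path: str | Path) -> Path:
    """Serialise the report deterministically (sorted keys, no timestamps)."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
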