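"""Flux fitting, bootstrap uncertainty, gas partitioning, Wald comparisons."""

import itertools

import numpy as np
import pytest
import scipy.stats

from wetflux.flux_fit import (
    bootstrap_fluxes,
    compare_fluxes,
    fit_fluxes,
    partition_gas,
)
from wetflux.reaction_network import (
    Metabolite,
    Reaction,
    ReactionNetwork,
)


def grid_search_nnls(S, b, v_max=0.5, step=1e-4, coarse=26, rounds=4):
    """Independent oracle: refine a dense grid around the best sum of squares.

    Searches [0, v_max]^k by repeated zooming until the grid spacing is below
    ``step``; feasible only for k <= 3.
    """
    k = S.shape[1]
    lo = np.zeros(k)
    hi = np.full(k, v_max)
    best = None
    while True:
        axes = [np.linspace(lo[j], hi[j], coarse) for j in range(k)]
        spacing = (hi - lo) / (coarse - 1)
        for point in itertools.product(*axes):
            v = np.array(point)
            ss = float(((S @ v - b) ** 2).sum())
            if best is None or ss < best[0]:
                best = (ss, v)
        if spacing.max() <= step:
            return best[1]
        center = best[1]
        span = 2.5 * spacing
        lo = np.maximum(center - span, 0.0)
        hi = center + span
        best = None


def toy_network(n_reactions):
    """<=3 balanced reactions over <=4 fitted species for oracle comparison."""
    mets = [
        Metabolite("glucose", "glucose", 6, 24, role="substrate"),
        Metabolite("acetate", "acetate", 2, 8),
        Metabolite("co2", "co2", 1, 0),
        Metabolite("h2", "h2", 0, 2),
        Metabolite("ch4", "ch4", 1, 8),
    ]
    rxns = [
        Reaction("acetogenesis", "a", {"glucose": -1, "acetate": 2, "co2": 2, "h2": 4}, "glucose"),
        Reaction("hydro_methano", "h", {"h2": -4, "co2": -1, "ch4": 1}, "ch4"),
        Reaction("aceto_methano", "m", {"acetate": -1, "ch4": 1, "co2": 1}, "ch4"),
    ]
    return ReactionNetwork(mets, rxns[:n_reactions], fitted_species=("acetate", "co2", "h2", "ch4"))


@pytest.mark.parametrize("n_reactions", [2, 3])
def test_nnls_matches_grid_search_oracle(n_reactions):
    net = toy_network(n_reactions)
    S = net.fitted_matrix()
    b = np.array([0.11, 0.44, 0.096, 0.29])
    est = fit_fluxes(net, dict(zip(net.fitted_species, b)))
    v_hat = np.array([est.flux[r] for r in net.reaction_ids])
    v_grid = grid_search_nnls(S, b)
    assert np.all(np.abs(v_hat - v_grid) <= 2e-4)


def test_zero_measurements_give_zero_fluxes(anoxic_net):
    est = fit_fluxes(anoxic_net, {m: 0.0 for m in anoxic_net.fitted_species})
    assert all(v == 0 for v in est.flux.values())
    assert all(r == 0 for r in est.residuals.values())


def test_noiseless_flux_recovery_is_exact(anoxic_net):
    v_true = {
        "hydrogenic_acetogenesis": 0.14,
        "acetoclastic_methanogenesis": 0.18,
        "hydrogenotrophic_methanogenesis": 0.14,
        "butyrate_production": 0.02,
        "lactate_fermentation": 0.005,
    }
    v = np.array([v_true.get(r, 0.0) for r in anoxic_net.reaction_ids])
    b = dict(zip(anoxic_net.fitted_species, anoxic_net.fitted_matrix() @ v))
    est = fit_fluxes(anoxic_net, b)
    for r in anoxic_net.reaction_ids:
        assert est.flux[r] == pytest.approx(v_true.get(r, 0.0), abs=1e-8)
    assert est.r_squared == pytest.approx(1.0, abs=1e-12)


def test_endpoint_fit_matches_reported_methanogenesis_extents(anoxic_net, condition_endpoints):
    """Anoxic baseline fit lands on the published methanogenesis extents."""
    b = {m: condition_endpoints["S-O-"][m] for m in anoxic_net.fitted_species}
    est = fit_fluxes(anoxic_net, b, condition="S-O-")
    assert est.flux["acetoclastic_methanogenesis"] == pytest.approx(0.18, abs=0.01)
    assert est.flux["hydrogenotrophic_methanogenesis"] == pytest.approx(0.14, abs=0.01)
    assert est.r_squared > 0.9


def test_fluxes_always_nonnegative(anoxic_net):
    rng = np.random.default_rng(7)
    for _ in range(20):
        b = dict(zip(anoxic_net.fitted_species, rng.normal(0, 0.2, 7)))
        est = fit_fluxes(anoxic_net, b)
        assert all(v >= 0 for v in est.flux.values())


def test_missing_metabolite_raises_by_name(anoxic_net):
    b = {m: 0.1 for m in anoxic_net.fitted_species if m != "ch4"}
    with pytest.raises(KeyError, match="ch4"):
        fit_fluxes(anoxic_net, b)


def test_weights_must_be_positive(anoxic_net):
    b = {m: 0.1 for m in anoxic_net.fitted_species}
    with pytest.raises(ValueError, match="positive"):
        fit_fluxes(anoxic_net, b, weights={m: 0.0 for m in anoxic_net.fitted_species})


def test_rank_deficient_system_flagged_not_fatal(net):
    # full 9-reaction network on 7 fitted species cannot have full column rank
    est = fit_fluxes(net, {m: 0.1 for m in net.fitted_species})
    assert any("rank_deficient" in w for w in est.warnings)
    assert all(v >= 0 for v in est.flux.values())


# ---------------------------------------------------------------------------
# bootstrap


def _replicates(b, n=3, jitter=0.0, rng=None):
    out = {}
    for m, mu in b.items():
        if jitter and rng is not None:
            out[m] = list(mu + rng.normal(0, jitter, n))
        else:
            out[m] = [mu] * n
    return out


def test_bootstrap_zero_spread_gives_zero_sd(anoxic_net, condition_endpoints):
    b = {m: condition_endpoints["S-O-"][m] for m in anoxic_net.fitted_species}
    reps = _replicates(b)
    est = bootstrap_fluxes(anoxic_net, reps, n_boot=100, seed=3)
    point = fit_fluxes(anoxic_net, b)
    assert all(sd == pytest.approx(0.0, abs=1e-12) for sd in est.flux_sd.values())
    for r in anoxic_net.reaction_ids:
        assert est.flux[r] == pytest.approx(point.flux[r], abs=1e-12)


def test_bootstrap_deterministic_under_seed(anoxic_net, condition_endpoints):
    rng = np.random.default_rng(11)
    b = {m: condition_endpoints["S-O-"][m] for m in anoxic_net.fitted_species}
    reps = _replicates(b, jitter=0.01, rng=rng)
    a = bootstrap_fluxes(anoxic_net, reps, n_boot=200, seed=5)
    c = bootstrap_fluxes(anoxic_net, reps, n_boot=200, seed=5)
    assert a.flux_sd == c.flux_sd
    assert a.seed == 5 and a.n_boot == 200


def test_bootstrap_requires_two_replicates(anoxic_net):
    reps = {m: [0.1] for m in anoxic_net.fitted_species}
    with pytest.raises(ValueError, match="replicates"):
        bootstrap_fluxes(anoxic_net, reps, n_boot=100, seed=1)


def test_bootstrap_sd_scale_matches_repeat_experiments(anoxic_net, endpoint_table):
    """Bootstrap SD of the acetoclastic flux sits within a factor of 3 of the
    SD seen when the whole endpoint experiment is redrawn many times."""
    sub = endpoint_table[endpoint_table["condition"] == "S-O-"]
    mu = dict(zip(sub["metabolite_id"], sub["mean_mmol_per_g_dry_soil"]))
    sd = dict(zip(sub["metabolite_id"], sub["sd_mmol_per_g_dry_soil"]))
    mu = {m: mu[m] for m in anoxic_net.fitted_species}
    sd_f = {m: sd[m] for m in anoxic_net.fitted_species}

    rng = np.random.default_rng(123)
    repeats = []
    for _ in range(20):
        reps = {
            m: list(np.maximum(rng.normal(mu[m], sd_f[m], 3), 0.0))
            for m in anoxic_net.fitted_species
        }
        est = bootstrap_fluxes(anoxic_net, reps, n_boot=300, seed=int(rng.integers(2**31)))
        repeats.append(est.flux_sd["acetoclastic_methanogenesis"])
    # replicate SDs at the endpoint-table scale imply an acetoclastic flux SD near 0.002
    assert 0.002 / 3 <= np.median(repeats) <= 0.002 * 3


# ---------------------------------------------------------------------------
# gas partition


def test_partition_single_contributor_is_all_of_production(anoxic_net, condition_endpoints):
    b = {m: 0.0 for m in anoxic_net.fitted_species}
    v = {"acetoclastic_methanogenesis": 0.18}
    bvec = anoxic_net.fitted_matrix() @ np.array(
        [v.get(r, 0.0) for r in anoxic_net.reaction_ids]
    )
    est = fit_fluxes(anoxic_net, dict(zip(anoxic_net.fitted_species, bvec)))
    part = partition_gas(anoxic_net, est)
    assert part.ch4_fraction["acetoclastic_methanogenesis"] == pytest.approx(100.0)
    assert part.co2["acetoclastic_methanogenesis"] == pytest.approx(0.18)


def test_partition_two_methanogenesis_routes(anoxic_net):
    v = {"acetoclastic_methanogenesis": 0.18, "hydrogenotrophic_methanogenesis": 0.14}
    bvec = anoxic_net.fitted_matrix() @ np.array(
        [v.get(r, 0.0) for r in anoxic_net.reaction_ids]
    )
    est = fit_fluxes(anoxic_net, dict(zip(anoxic_net.fitted_species, bvec)))
    part = partition_gas(anoxic_net, est)
    assert part.ch4_fraction["acetoclastic_methanogenesis"] == pytest.approx(56.25, abs=1e-6)
    assert part.ch4_fraction["hydrogenotrophic_methanogenesis"] == pytest.approx(43.75, abs=1e-6)
    assert part.co2["hydrogenotrophic_methanogenesis"] == pytest.approx(-0.14)


def test_partition_conserves_predicted_net_gas(anoxic_net, condition_endpoints):
    b = {m: condition_endpoints["S-O-"][m] for m in anoxic_net.fitted_species}
    est = fit_fluxes(anoxic_net, b)
    part = partition_gas(anoxic_net, est)
    predicted_co2 = b["co2"] + est.residuals["co2"]
    predicted_ch4 = b["ch4"] + est.residuals["ch4"]
    assert sum(part.co2.values()) == pytest.approx(predicted_co2, abs=1e-12)
    assert sum(part.ch4.values()) == pytest.approx(predicted_ch4, abs=1e-12)
    for fracs in (part.co2_fraction, part.ch4_fraction):
        assert sum(fracs.values()) == pytest.approx(100.0, abs=1e-9)


def test_partition_all_zero_fluxes_reports_null_fractions(anoxic_net):
    est = fit_fluxes(anoxic_net, {m: 0.0 for m in anoxic_net.fitted_species})
    part = partition_gas(anoxic_net, est)
    assert part.co2_fraction is None and part.ch4_fraction is None


# ---------------------------------------------------------------------------
# Wald comparisons


def _est(flux, sd, n_boot=100):
    from wetflux.flux_fit import FluxEstimate

    return FluxEstimate(
        condition=None, flux=flux, residuals={}, r_squared=1.0,
        flux_sd=sd, n_boot=n_boot,
    )


def test_wald_equal_fluxes_give_p_one():
    a = _est({"r": 0.2}, {"r": 0.01})
    b = _est({"r": 0.2}, {"r": 0.02})
    (res,) = compare_fluxes(a, b, "r")
    assert res.statistic == 0 and res.p == 1.0


def test_wald_statistic_closed_form_and_tail():
    a = _est({"r": 0.33}, {"r": 0.005})
    b = _est({"r": 0.0}, {"r": 0.005})
    (res,) = compare_fluxes(a, b, "r")
    assert res.statistic == pytest.approx(0.33**2 / (2 * 0.005**2))
    assert res.statistic == pytest.approx(2178.0)
    assert res.p == pytest.approx(float(scipy.stats.chi2.sf(2178.0, 1)))
    assert res.p < 1e-100


def test_wald_degenerate_variance_flagged():
    a = _est({"r": 0.1}, {"r": 0.0})
    b = _est({"r": 0.0}, {"r": 0.0})
    (res,) = compare_fluxes(a, b, "r")
    assert res.degenerate_variance and res.p == 0.0


def test_bh_adjustment_worked_example():
    """p = (0.01, 0.02, 0.03) -> q = (0.03, 0.03, 0.03) under BH."""
    # build three reactions whose Wald p-values are 0.01/0.02/0.03
    diffs = {r: scipy.stats.chi2.isf(p, 1) for r, p in zip("abc", (0.01, 0.02, 0.03))}
    a = _est({r: float(np.sqrt(2) * 0.1 * np.sqrt(s)) for r, s in diffs.items()},
             {r: 0.1 for r in diffs})
    b = _est({r: 0.0 for r in diffs}, {r: 0.1 for r in diffs})
    results = compare_fluxes(a, b, list(diffs))
    ps = [res.p for res in results]
    assert ps == pytest.approx([0.01, 0.02, 0.03])
    assert [res.q for res in results] == pytest.approx([0.03, 0.03, 0.03])


def test_wald_requires_bootstrap():
    a = _est({"r": 0.1}, {"r": 0.01}, n_boot=0)
    b = _est({"r": 0.1}, {"r": 0.01})
    with pytest.raises(ValueError, match="bootstrap"):
        compare_fluxes(a, b, "r")
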