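# wetflux

Stoichiometric flux analysis of wetland soil microcosms under sulfate and
oxygen perturbation.

Wetland soils are large methane and carbon dioxide sources whose emissions
shift when drought lets oxygen in or seawater intrusion raises sulfate. This
package quantifies those shifts for laboratory microcosm experiments run
under four redox conditions — anoxic/oxic crossed with and without sulfate
addition (`S-O-`, `S+O-`, `S-O+`, `S+O+`): it fits the extents of nine
guild-level overall reactions to cumulative metabolite accumulations,
attributes CO₂ and CH₄ production and consumption to individual guilds, does
the carbon- and electron-balance bookkeeping of the geochemical data, and
rolls metaproteome protein abundances up to species, guilds and diversity
indices. It is written for biogeochemists and microbial ecologists who have
bottle-scale incubation data (gas chromatography, HPLC organics, sulfide
measurements) and want a food-web-level account of where carbon and
electrons went.

## The model

A guild-level reaction network (aerobic heterotrophy, lactate fermentation,
hydrogenic acetogenesis, sulfidogenic lactate and H₂ oxidation,
hydrogenotrophic and acetoclastic methanogenesis, methane oxidation,
butyrate production) defines a stoichiometric matrix **S**. Restricting to
the seven measured species (acetate, lactate, butyrate, H₂, CO₂, CH₄, H₂S)
gives **S**_f, and the vector of cumulative net amounts **b** (mmole per g
dry soil over the incubation) determines non-negative reaction extents

```
v̂ = argmin_{v ≥ 0} ‖ W (S_f v − b) ‖²
```

solved by non-negative least squares, with optional diagonal weighting **W**.
Reactions whose electron acceptor is absent (O₂-dependent reactions under
anoxic incubation, sulfate-dependent ones without sulfate addition) are
removed from the active set before fitting. Every reaction balances carbon
and available electrons exactly (rational arithmetic): e.g. glucose carries
24 e⁻/mole, acetate 8, CH₄ 8, H₂ 2, sulfide 8 (the electrons accepted per
sulfate reduced), and O₂ accepts 4 per mole. Uncertainty comes from a
parametric bootstrap over replicate variation; fluxes are compared across
conditions with Wald χ² tests, Benjamini–Hochberg adjusted.

## Worked example

The endpoint accumulations of the four conditions ship with the package
(30-day means ± SD, mmole per g dry soil). Fitting them:

```python
import wetflux as wf

report = wf.run_pipeline(wf.load_endpoints(), n_boot=500, seed=1)
for cond in report["conditions"]:
    print(cond, round(report["fits"][cond]["r_squared"], 4))
print(report["partitions"]["S-O-"]["ch4_production_pct"])
print(report["electron_molarity"]["S-O-"]["ch4"])
```

prints

```
S-O- 0.9876
S+O- 0.9923
S-O+ 1.0
S+O+ 1.0
{'hydrogenotrophic_methanogenesis': 44.00520579144299,
 'acetoclastic_methanogenesis': 55.994794208557}
2.32
```

Read: the nine-reaction model explains the measured metabolite pattern with
R² > 0.98 in every condition. Under the anoxic baseline, 56% of CH₄ comes
from acetate cleavage and 44% from H₂/CO₂; 2.32 mmole of electrons per gram
dry soil ended up in CH₄. The report also carries per-reaction CO₂/CH₄
amounts (hydrogenotrophic methanogenesis *consumes* CO₂ — one reason sulfate
addition, which halts it, raises CO₂), treatment effect sizes (sulfate cuts
CH₄ 3.7-fold; oxygen raises CO₂ 1.7-fold), synergy/antagonism
classifications, and Wald tests of each flux against the baseline.

The same analysis is available from the shell:

```bash
wetflux run --measurements packaged --seed 42 --out report.json
wetflux simulate --out sim.csv --proteome prot.tsv   # synthetic study
wetflux fit --measurements sim.csv --condition S+O- --out fit.json
wetflux proteome --table prot.tsv --endpoints sim.csv --out proteome.json
wetflux geochem --bottles bottles.csv --out amounts.csv
```

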