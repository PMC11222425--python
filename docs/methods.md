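# Methods

## The reaction network

The community is represented by nine overall reactions, each lumping one
functional guild's catabolism and written per mole of a reference species
(starred):

| reaction | stoichiometry | active when |
|---|---|---|
| aerobic heterotrophy | −1 glucose* − 6 O₂ → 6 CO₂ | oxic |
| lactate fermentation | −1 glucose* → 2 lactate | always |
| hydrogenic acetogenesis | −1 glucose* → 2 acetate + 2 CO₂ + 4 H₂ | always |
| sulfidogenic lactate oxidation | −2 lactate − 1 SO₄²⁻* → 2 acetate + 2 CO₂ + 1 H₂S | sulfate added |
| sulfidogenic H₂ oxidation | −4 H₂ − 1 SO₄²⁻* → 1 H₂S | sulfate added |
| hydrogenotrophic methanogenesis | −4 H₂ − 1 CO₂ → 1 CH₄* | always |
| acetoclastic methanogenesis | −1 acetate* → 1 CH₄ + 1 CO₂ | always |
| methane oxidation | −1 CH₄* − 2 O₂ → 1 CO₂ | oxic |
| butyrate production | −1 glucose* → 1 butyrate + 2 CO₂ + 2 H₂ | always |

These are the textbook overall transformations for each guild, chosen so
that every reaction balances carbon and available electrons exactly; the
network is user-replaceable through three TSV files (metabolites, reaction
metadata, stoichiometry with exact rational coefficients), so an alternative
set — e.g. fermentations starting from lactate rather than glucose — can be
swapped in without code changes. Water and protons are omitted: they are
unmeasured and do not enter the objective. One unit of flux is one mole of
the reaction as written, anchored at the reference species, in mmole per
gram dry soil over the incubation.

**Electron bookkeeping.** Each metabolite carries integer available-electron
equivalents per mole (degree of reduction against the CO₂/H₂O/SO₄²⁻
reference): glucose 24, lactate 12, butyrate 20, acetate 8, H₂ 2, CH₄ 8,
CO₂ 0. Sulfide is assigned 8 e⁻/mole — the electrons accepted per sulfate
reduced to sulfide — and sulfate itself enters the balance at zero, so the
acceptance is recorded once, on the product. O₂ is a pure acceptor at
4 e⁻/mole consumed. A reaction balances when donated electrons equal product
electrons plus O₂ uptake; this is asserted in rational arithmetic for every
network at construction time. The same per-mole equivalents drive the
electron-molarity summaries (0.29 mmole/g CH₄ ⇒ 2.32 e-mmole/g).

## Flux estimation

Extents are fit by non-negative least squares (Lawson–Hanson, via
`scipy.optimize.nnls`) against the cumulative net amounts of the seven
fitted species at the incubation endpoint, averaged over replicate bottles.
Glucose and O₂ are excluded from the objective: the hydrolysate supply and
oxygen regime are boundary conditions, not fitted observations. The fit is
unweighted by default (1/SD weighting is available but the replicate SDs
span two orders of magnitude and would let the near-zero sulfide
measurements dominate). Goodness of fit is R² = 1 − SS_res/SS_tot over the
(weighted) fitted entries about the data mean.

**Identifiability.** The active set under anoxic, non-sulfate conditions
(five reactions) has full column rank on the seven fitted species, so the
zero-noise fit recovers true extents exactly. The other active sets carry
exact linear dependencies once glucose is dropped from the objective — e.g.
lactate fermentation + sulfidogenic lactate oxidation produces the same
fitted-species signature as hydrogenic acetogenesis + sulfidogenic H₂
oxidation, and under oxic conditions fermentation + methanogenesis + methane
oxidation composes to aerobic heterotrophy. There the data determine the
predicted metabolite pattern uniquely but not the flux split along the
degenerate direction; the solver returns a vertex of the optimal face and a
`rank_deficient` flag is attached to the estimate. Interpretation of
individual fluxes under those conditions should lean on the proteome
evidence for which guild was active.

**Uncertainty.** A parametric bootstrap resamples each fitted metabolite
from Normal(replicate mean, replicate SD), truncated at zero because the
amounts are cumulative productions, then refits; the flux SD is the sample
SD over (default) 1000 refits, fully determined by the seed (default 42,
always echoed into outputs). Between-condition contrasts use the pairwise
Wald statistic (vA − vB)²/(sdA² + sdB²) on 1 df with Benjamini–Hochberg
adjustment across the reactions compared in one call; this is the plain
Wald form of the χ² flux comparison, not a model-based type-II ANOVA.

**Partitioning.** Reaction j contributes S[gas, j]·v̂_j of each gas (signed);
production percentages are taken over positive contributors only, so
consumption (CO₂ uptake by hydrogenotrophic methanogenesis, CH₄ uptake by
methanotrophy) is reported in absolute terms alongside.

An endpoint fit is the default because cumulative 30-day amounts are the
quantity the extents parameterise; fitting all sampling days jointly under a
shared monotone activity profile changes nothing at the endpoint and is
deferred.

## Geochemical conversions

Headspace amounts follow the ideal gas law n = x·P·V/(R·T) with
R = 8.314 L·kPa·mol⁻¹·K⁻¹. Total sulfide adds to the gas-phase amount a
dissolved pool C_gas·H_cc·V_liq·(1 + 10^(pH−pKa1)), with the dimensionless
Henry solubility H_cc = 2.45 and pKa1 = 6.98 (30 °C values, both
configurable); the second dissociation is ignored since pKa2 ≈ 12–13 far
exceeds slurry pH, and ionic-strength corrections are omitted. Amounts are
normalised by slurry mass × dry fraction, default dry fraction 0.229 as
determined gravimetrically at the endpoint. Treatment effects are reported
as signed percent change and as max/min fold change with a direction flag;
two-stressor interactions are classified synergistic/antagonistic/additive
by comparing |combined effect| with |sum of single effects| (tolerance 0 by
default — the classification is descriptive, not a hypothesis test).

## Metaproteome summaries

Protein abundances (normalised label-free intensities) roll up to species by
summation, with a protein identified in k species contributing 1/k of its
abundance to each — abundance is conserved exactly. Richness counts species
with nonzero abundance; evenness is Pielou's J = H/ln(richness) (undefined
for richness ≤ 1). Guild totals are correlated with gas endpoints by Pearson
r, p from the t statistic on n−2 df. Differential protein abundance between
conditions uses log₂ fold change of group means (pseudo-abundance 10⁻⁶ ×
median nonzero abundance guards zero entries), Welch's t-test and
Benjamini–Hochberg q-values with the conventional q < 0.05 threshold; this
deliberately simple two-group procedure replaces a negative-binomial GLM and
is recorded in the output metadata, so results should be read as effect-size
screens rather than count-model inference.

## Synthetic data generator

The generator emulates the study design: four conditions × three replicate
bottles sampled on days 2, 9, 16, 23 and 30. Cumulative amounts are
f(day)·(S v_cond) plus independent Gaussian noise truncated at zero wherever
the noiseless cumulative production is nonnegative; f is a shared monotone
activity profile (default 0.1, 0.4, 0.65, 0.85, 1.0 — fast early
fermentation, then saturation) reaching 1 on the final day. Default true
extents are the magnitudes fitted from the packaged endpoint table, and
default noise SDs are the reported endpoint replicate SDs (CO₂ 0.02, CH₄
0.007, acetate 0.012 mmole/g, ...). Proteomes are log-normal protein
abundances (σ = 0.6) with multiplicative guild×condition effects shaped
after the observed guild shifts, replicate noise of CV ≈ 0.15, and a
configurable fraction of proteins shared between two species to exercise
the split rule.

What the generator does **not** emulate: between-day autocorrelation,
per-reaction activity profiles, phase-transfer kinetics, compositional
closure of proteome intensities, and fitting-model misspecification (the
simulated data are generated by the same stoichiometry that fits them). A
passing closed loop therefore validates estimator correctness and
uncertainty calibration, not the adequacy of the nine-reaction model for
any particular field soil.

## Problem sizes and numerical choices

Validation uses 50 zero-noise draws per condition (flux recovery to 1e-8
where the active set is full rank, measurement-space recovery elsewhere),
200 simulated experiments at the default noise scale for bias and bootstrap
calibration (bias < 10% of truth; bootstrap SD within 3× of the
across-experiment SD), and grid-search refinement to 1e-4 as an independent
NNLS oracle on ≤3-reaction toys. Coefficients are exact `fractions.Fraction`
rationals in the network definition and float64 in the solver; balance
checks never tolerate rounding. Tie-breaks in degenerate fits follow the
Lawson–Hanson active-set path and are deterministic. All-zero measurements
yield all-zero fluxes and undefined (null) production fractions; reports
serialise with sorted keys and no timestamps, so identical inputs and seeds
produce byte-identical JSON.
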