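# Methods

This note documents the models implemented in `bioscrub`, the
assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open.

## Scope and architecture

The package compares two flue-gas desulfurization trains treating the
off-gas of a sulfur-burning pigment plant:

* **CS** — a caustic spray scrubber whose liquor recirculates over the
  column; absorbed S(IV) accumulates until a small continuous purge
  carries it out as brine.
* **BS** — the same absorber followed by a sulfidogenic UASB reactor
  (sulfate/sulfite reduction on glycerol) and a micro-aerobic stirred
  tank that partially oxidizes the sulfide to elemental biosulfur, which
  is centrifuged, dried and returned to the furnace. Two variants differ
  only in the carbon source purchased: fossil pure glycerin (BS-PG) or
  purified crude glycerol at 95% glycerol content (BS-PCG).

Each stage is a separate module with an explicit steady-state solver;
the plant module wires them into a recycle loop and emits an annualized
life-cycle inventory, which the LCIA and LCC layers characterize, 
normalize, price and discount. A sweep engine re-runs the whole chain
over 2-D parameter grids.

## Acid-base chemistry (`chemistry`)

All liquid stages share one speciation model. Fractions of each
protonation state follow the cumulative-Ka partition function evaluated
in log space; pH comes from a bracketed Brent solve of the
electroneutrality balance on pH ∈ [0, 14], which is monotone for acids
whose charge falls with deprotonation, so the root is unique. Dosing to
a pH set point is exact: the NaOH (or HCl) dose equals the negated
charge residual at the target pH.

Constants (25 °C, zero ionic strength): carbonate pKa 6.35/10.33,
sulfide pKa1 7.05 (the disputed second ionization is negligible at
process pH and omitted), sulfurous 1.85/7.2. Sulfate is treated as a
fully dissociated strong anion. Activities are identified with
concentrations — at the ionic strengths of the CS brine (≈1 M) this
overestimates effective constants by tens of percent, which is absorbed
by the transfer-coefficient calibration below. Temperature dependence is
excluded, as temperature is not a state variable of the plant model.

## Absorber (`absorber`)

A counter-current cascade of well-mixed gas–liquid stages (default 5;
total liquid holdup 3.7 m³). Per stage and species,

```
T = kLa · V_stage · (p/H − α₀(pH) · C_total)      [mol h⁻¹]
```

with `H` a Henry volatility constant (atm L mol⁻¹: SO2 0.81, CO2 29.4,
H2S 9.8) and `α₀` the neutral fraction from the stage's own pH solve —
only the neutral dissolved species exerts a back pressure, the ionic
forms are held by speciation. Gas totals are re-balanced stage by stage,
so outlet ppmv reflects the changed total molar flow rather than naive
`inlet × (1 − η)` scaling. The solver alternates a gas march (with an
inner self-consistent total-flow iteration) and a liquid march
(two-species root per stage), under-relaxing on oscillation; sulfur
closure at convergence is at solver precision (≪10⁻⁶ relative).

**Calibration.** The published mass-transfer correlation for the spray
column is not reproducible from public information, so a single
dimensionless `kla_scale` multiplies all kLa values. It is fitted once
so the CS loop's SO2 absorption efficiency equals 59.3% at the baseline
operating point (fitted value 1.8831), and then left alone. The BS columns are *not* fitted:
their marginally higher efficiency (59.32% vs the CS 59.30%, against
a 59.9% reference value, i.e. within 1%) emerges
from the cleaner, bicarbonate-buffered loop liquor.

## Sulfidogenic UASB (`uasb`)

A chain of mini-CSTRs (default 10) captures the plug-flow-like behavior
of the granular bed. The biochemical engine is data-driven: a reaction
matrix (reactions × species) plus Monod kinetics and a trophic-group tag
per reaction. The shipped default has 15 reactions — 8 fermentative
(glycerol → 1,3-propanediol / propionate / acetate+H2 / butyrate+H2 and
the secondary fermentations of those intermediates), 5 sulfate-reducing
(H2, acetate, propionate, butyrate, glycerol as electron donors) and 2
methanogenic (acetoclastic, hydrogenotrophic). Units: organics and
biomass in g COD L⁻¹, sulfur species in g S L⁻¹, with sulfide carrying
2 g COD per g S — this convention closes the COD balance across sulfate
reduction exactly. Every matrix is validated at load: per-reaction COD
and S closure to 10⁻⁶ relative, and loading fails loudly otherwise.
The inorganic-carbon column of each default reaction is *computed* as
the complement of the organic-carbon balance (contents per g COD:
glycerol 0.321, acetate 0.375, CH4 0.1875, biomass 0.374 as C5H7O2N),
so fermentation returns CO2/bicarbonate to the liquor. This alkalinity
is load-bearing: recycled bicarbonate is what buffers the bioscrubber's
absorber liquor (and what pushes its CO2 outlet above the inlet).

Rates use the growth convention `ρ = μmax·X·S/(Ks+S)·[SO4 dual
Monod]·Ki/(Ki+S_sulfide)` with non-competitive sulfide inhibition on all
groups (Ki: fermenters 0.50, sulfate reducers 0.25, methanogens 0.08
g S L⁻¹ — strongest on methanogens). Granular biomass is a retained
inventory (time-invariant concentration per group) rather than a
suspended state; setting `retention = 0` recovers a classical chemostat,
which is how the solver is verified against the washout closed form
`S* = Ks·D/(μmax − D)`. Biomass grown on a retained bed is reported as
sludge production and enters the COD audit.

Gas transfer acts on the top compartment only, with kLa = 200 d⁻¹,
against a headspace held near 1.05 atm by an outflow valve; the vent is
the biogas stream. Steady states are found by LSODA integration plus a
Newton polish on the full right-hand side (warm restarts skip the
integration when a previous solution is close).

**Calibration.** The published kinetic parameter set for this reactor is
not reproducible from public information; the retained sulfate-reducer
inventory `x_srb` is the single fitted scalar (0.386 g COD L⁻¹),
anchored so the treated effluent carries 0.3 g L⁻¹ of
SO4²⁻-equivalents at baseline. The
glycerol dose ratio (5.746 g COD per g S fed) is anchored to the
baseline annual glycerin purchase of 4,094.6 t yr⁻¹. Absorbed S(IV) and recycled
S(VI) are lumped into a single electron-acceptor pool ("sulfate");
sulfite is the easier acceptor, so lumping is conservative.

## Sulfide oxidation tank (`oxidizer`)

A single aerated CSTR (2,277 m³) with a three-step sulfur-oxidizing
chain (sulfide→S⁰ at low oxygen half-saturation, S⁰→sulfate suppressed
at low DO, thiosulfate→sulfate), a small abiotic sulfide→thiosulfate
route, and one aerobic heterotrophic process on residual COD with
activated-sludge-typical defaults (μmax 6 d⁻¹, Ks 4 g COD m⁻³, Y 0.63).
Partial-oxidation selectivity toward elemental sulfur is therefore a
monotone function of the DO level, which a PI controller holds at
0.1 mg O2 L⁻¹ by manipulating the air flow; kLa follows a power law
`α (Q/V)^β` (α = 43.3 fitted so the baseline air demand is 100 m³ h⁻¹,
β = 0.8). The discrete controller clamps its output to the blower range
and freezes the integral while pinned (anti-windup). The steady-state
fast path pins DO at the set point — integral action guarantees this
whenever the demand is inside the actuator range — and recovers the air
flow from the oxygen balance; infeasible demand is flagged, never
silently absorbed.

## Plant loop, energy and inventory (`plant`)

The recycle tear (absorber-inlet liquor: S(IV), carbonate, sulfide,
sulfate pool) is solved as a steady-state root problem (spectral
residual method with a Newton fallback, finished by an
extrapolated-substitution polish that converges the loop's slow
accumulation mode and makes the answer independent of warm starts). Dosing to the pH set point
pins the liquor's strong-cation level analytically, which removes the
slowest loop mode; NaOH *consumption* is the dosed cation level times
the loop loss fraction (purge + centrifuge cake). Make-up water equals
purge + absorber evaporation (1.594·10⁻⁵ m³ water per m³ gas, anchored
to the baseline freshwater line) + cake water, so the water balance
closes by construction.

Energy: available heat is the flue-gas sensible heat from 400 to 80 °C
(molar cp 29.2 J mol⁻¹ K⁻¹); demands are reactor-jacket heating of the
biological feed from 25 to 35 °C and drying of the centrifuge cake from
65% to 10% moisture with 140 °C air (2.5 MJ per kg water evaporated,
latent plus sensible). The ratio of demand to availability at the
baseline is ≈78%; a single fitted draw factor (0.915) aligns the
reported recovery with the 71.1% reference value. Pump electricity is ρgQH/η
with per-pump heads fitted to the metered baseline kWh lines at η = 0.7
(e.g. recirculation: 20.82 m at 220 m³ h⁻¹ → 156,210 kWh yr⁻¹); the
"transformation" inventory line is the service sum of all electricity
lines and is excluded from energy costing to avoid double counting.

Known limitation: with a 1% purge and full conservation (enforced to
10⁻⁶ relative by the acceptance suite), the loop necessarily recovers
≈85–90% of the *absorbed* sulfur as biosulfur — the only other exits are
the dilute purge, biogas H2S and stripping. A recovery near 50% of
absorbed S would require an S exit that the flowsheet does not have;
the reported ratio is therefore the conserving one, and both
recovered/absorbed and recovered/inlet ratios are exposed.

## LCIA (`lcia`)

Characterization is a factor matrix (18 midpoint categories × inventory
lines) times the inventory vector; negative (byproduct) lines yield
avoided impacts. Normalization divides by per-category
person-equivalent factors; categories are ranked by |PE| and the
smallest prefix reaching 95% coverage is selected, with GWP always
included. The pairwise comparison statistic is

RIR = (IC_BS − IC_CS) / max(IC_BS, IC_CS),

classified green (< −0.5: the chemical scrubber carries the higher
impact), yellow (comparable; boundary values inclusive) or red (> 0.5).
With net-avoided categories the same formula may leave [−1, 1]; the
value is flagged, not clamped. Contribution shares per category are
signed and normalized by the sum of absolute component values
(Resources / Energy / End of life / Air emissions / Byproducts).

Licensed characterization databases are data, not code: the repository
generates *synthetic* factor tables (seeded, positive, keyed to the
inventory line names). Everything structural — ratios, classes,
rankings, coverage selection — is exact on any table; absolute impact
values computed from the synthetic tables are placeholders.

## LCC (`lcc`)

Costs are negative, revenues positive. NPV = I₀ + Σ R_t/(1+i)^t with
the year-0 investment undiscounted, i = 1.5%, N = 20 years, nominal
2021 €. The printed baseline NPVs are not reproducible from the printed
cashflows under any standard convention we tried, so the suite asserts
the discounting identities (annuity closed form, zero-interest sum,
cumulative-present-value consistency) rather than those cells. IRR is
reported as NaN for uniform-sign flows — with only the treatment line in
scope all cashflows are negative and the IRR has no root — and the
cumulative present value is the discount-rate sensitivity view.

Unit prices: NaOH 527 € t⁻¹, pure glycerin 745 € t⁻¹, purified glycerol
520 € t⁻¹, sulfur 150 € t⁻¹, electricity 0.088 € kWh⁻¹, natural gas
0.354 € m⁻³ and 68.9 € MWh⁻¹, freshwater 0.06 € m⁻³, wastewater
7.23 € m⁻³. Biogas is valued as avoided natural gas through its methane
energy content (9.97 kWh per m³ CH4) at the €/MWh gas price, which is
also the breakeven-surface axis. Labor is wage × 37.5 h × 52 weeks ×
1.35 tax wedge × FTE with FTE counts fitted to the baseline labor lines;
investment is linear in reactor volume (absorber 6,000 € m⁻³ plus a
fixed block; bioreactors 900 € m⁻³ plus a fixed bio block) and the
maintenance classes (2% scrubber / 5% reactors / 10% other) are applied
to a fitted split of each scenario's investment. All fitted economic
constants reproduce their baseline anchors to printed rounding and are
asserted in the test suite.

The breakeven surface recomputes the bioscrubber NPV per grid cell by
scaling the carbon-source cost line with the glycerol price and the
biogas revenue with the gas price; the iso-line where NPV_BS = NPV_CS
is linearly interpolated between sign changes. An empty iso-line is a
valid result, not an error.

## Sweeps (`sweeps`)

Axes: gas flow, inlet SO2, purge fraction, disposal distance. Every
cell runs the full pipeline for both scenarios of the pair. Bioreactor
volumes scale with the inlet S load and the absorber holdup with gas
flow, keeping residence times representative and letting investment
respond to plant size. Cells are warm-started from the *baseline*
solution only, never from neighbors, so results are independent of
evaluation order and bit-identical across repeat runs; per-cell
failures are recorded and leave NaN cells without aborting the sweep.

## Synthetic data and what passing tests show

The synthetic-data layer has two distinct parts. The *plant model
inputs* (Table-style operating conditions, prices) are the real baseline
values and defaults. The *LCIA factor tables* are synthetic stand-ins
for licensed data; tests passing on them demonstrate the correctness of
characterization arithmetic, normalization, selection, classification
and sweep plumbing — not reference absolute impact scores, which
require the licensed databases. Likewise, the default UASB matrix is an
engineered, balance-closed surrogate for an unavailable published
parameter set: simulations reproduce the calibrated baseline anchors and
conservation laws, but parameter-level agreement with the original
reactor model is not claimed.

## Numerical choices

* pH root: Brent on [0, 14], residual tolerance 10⁻¹⁰ mol L⁻¹.
* Absorber stage iteration: relative tolerance 10⁻¹², adaptive
  under-relaxation, hard iteration cap with a diagnostic error.
* UASB: LSODA (rtol 10⁻⁸, atol 10⁻¹⁰) then `hybr` polish; steady flag at
  max |dC/dt| < 10⁻⁸ of scale.
* Plant tear: df-sane capped at 120 evaluations, `hybr` fallback.
* Oxidizer PI simulation: zero-order-hold sampling at 0.05 h.
* Degenerate inputs: zero gas flow defines 0% heat recovery; both-zero
  impacts define RIR 0; boundary RIR values classify as comparable.

## Problem sizes used in the shipped runs

Baseline solves use 5 absorber stages, 10 mini-CSTRs × 13 species + 4
headspace states, and an 8-state oxidation tank. The test suite's sweep
exercises 2×2 grids with 4 mini-CSTRs per reactor; the acceptance
script runs the three scenario pipelines at full size plus the economic
and comparison layers. These sizes were chosen to keep a complete run
interactive on a laptop while leaving every numerical tolerance at its
production value.
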