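# Methods

This note documents the models and procedures implemented in `marinegem`,
the assumptions behind them, the parameters that matter, and the design
choices made where the underlying protocols leave the design open.

## Flux balance analysis

A metabolic model is held as explicit `Metabolite`/`Reaction` records; the
stoichiometric matrix is assembled on demand and the FBA linear program
`max cᵀv  s.t.  Sv = 0, v_min ≤ v ≤ v_max` is solved with HiGHS through
`scipy.optimize.linprog`. Conventions:

- Exchange reactions are written `metabolite ↔ ∅`; uptake is negative
  flux. `set_medium` edits only exchange bounds and never mutates its
  input model.
- The biomass reaction consumes 1 g of components per gCDW formed, so its
  flux is the growth rate in 1/h; all other fluxes are mmol/gCDW/h.
- Infeasible or unbounded programs are reported as solution statuses, not
  exceptions: both are legitimate outcomes of a medium choice.
- Tolerances: solver feasibility is HiGHS's (~1e-9); tests assert mass
  balance and bound satisfaction at 1e-6. Optimal flux *vectors* are
  generally not unique (alternate optima); only objective values, and
  summary statistics over fluxes, are contractual.

SBML input/output uses python-libsbml with Level 3 and the
flux-balance-constraints (fbc v2) extension. Bounds and the active
objective are required: a file without them is rejected rather than
silently defaulted, because a defaulted bound changes the feasible set.
SBML compartment ids map onto the three-compartment scheme
(cytoplasm/periplasm/extracellular) through a configurable table
(`c`/`cyt`, `p`/`per`, `e`/`ext` by default).

`model_stats` classifies a reaction as exchange if it touches exactly one
metabolite, transport if its metabolites span at least two compartments,
and internal otherwise. For bidirectional diffusion reactions this split
is a convention; the totals are the robust quantities.

## Salt-corrected dry weight

Cells grown at seawater osmolarity cannot be washed in water (osmotic
lysis), so pellets are washed in NaCl solution and weighed wet and dry.
With x, y the dry/wet weights (mg), w the harvested amount (OD600·mL), ρ
the wash salinity (mg NaCl per mg water) and β the assumed cellular water
per CDW (mg/mg), the dry pellet is cell mass plus residual salt
(`αw = x − ρz`) and the wet pellet adds cellular plus extracellular water
(`z = y − x − βαw`), giving

    α = (x(1+ρ) − ρy) / (w(1 − ρβ)).

β defaults to 2 mg/mg (rod-shaped Gram-negative reference value) with a
±1 band that is propagated into a reported α interval; the pellet itself
bounds β by y/x − 1 (equality is the valid zero-extracellular-water
boundary, enforced with a 1e-9 relative tolerance). Because ρ ≈ 0.03, α
varies with β only through the (1−ρβ)⁻¹ factor — a few percent over the
whole plausible β range, which is why the assumed β is safe. At ρ = 0 the
estimate reduces to x/w and β drops out entirely.

The add-back regression rewrites the same balance as a line of y on x
across aliquots differing only in retained wash solution; ordinary least
squares (the protocol reads slope and x-intercept off that plot; no
errors-in-variables correction) gives ρ̂ = 1/(slope−1) and
α = x₀(1+ρ̂)/((1−ρ̂β)w). ρ is otherwise a *measured* input; the package
never derives it from molarity.

## Biomass composition

RNA, protein and CDW per OD600·mL are linear in growth rate. The
reference fits (mg/(OD600·mL) as functions of μ in 1/h) are

    RNA: 0.05 μ + 0.05     protein: −0.09 μ + 0.38     CDW: −0.13 μ + 0.64

valid on μ ∈ [0, 1.38]. Mass fractions at μ are the channel lines divided
by the CDW line. Glutamate, the dominant osmolyte at seawater osmolarity,
is a fixed 5.0% of CDW (no clear growth-rate trend in the data it
represents); glutamine defaults to 0.5% (an order of magnitude below
glutamate). The residual mass is distributed over DNA, LPS, lipids,
murein, inorganic ions and soluble pools in the proportions of an
iAF1260-like reference table (those components sum to 20% of the
reference organism's CDW) scaled to fill whatever the measured components
leave — keeping relative proportions is the stated curation rule, and the
sensitivity scan below justifies not refining it.

Monomer profiles are genome tallies: every CDS is translated with the
standard code (minus-strand features reverse-complemented, start Met
counted, stops excluded, ambiguous residues skipped with a warning,
non-multiple-of-3 CDS skipped with a warning); rRNA genes give the RNA
nucleotide fractions (T read as U) since rRNA dominates cellular RNA; DNA
fractions are whole-genome counts over both strands. Frequencies are
unweighted by expression — the standard genome-tally approximation, which
inherently weights longer genes.

Biomass-reaction coefficients: a polymer class with mass fraction f and
monomer molar fractions φᵢ of residue mass mᵢ consumes monomer i at
1000·f·φᵢ/Σφⱼmⱼ mmol/gCDW; residue masses are free-monomer masses minus
18.02 g/mol of polymerization water (the standard convention; osmolytes
and lumped components use free/representative molar masses). GAM is
appended as gam × (ATP + H₂O → ADP + Pᵢ + H⁺).

The sensitivity scan rescales one component's coefficients at a time by
factors in [0.75, 1.25] *without renormalizing* the rest (the perturbation
is to the mass fraction itself; renormalizing would cancel it) and
re-solves FBA under a fixed medium, reporting the worst relative change in
μ. Components that are not flux-limiting move the optimum by effectively
nothing, which is what licenses borrowing their coefficients from a
reference organism.

## Maintenance energetics from batch cultures

Chemostats give maintenance parameters directly, but wild marine isolates
foam, flocculate and form biofilms; batch cultures on substrates with
different maximal growth rates provide the same spread of μ. Per culture:

- growth rate = OLS slope of ln(OD600) vs time (exponential phase only);
- consumption yield = −(OLS slope of substrate mM vs OD600) × carbons,
  in mM of carbon atoms per OD600; acetate (2 carbons) analogously for
  the excretion yield, with an all-zero acetate channel short-circuited
  to zero. Yields are regressed against OD, not time, so they are
  sampling-grid invariant. Acetate is the only overflow product modeled.
- carbon utilization rate = (consumption − excretion) × μ, the carbon
  that is either built into biomass or burned for energy.

Across cultures, carbon utilization is linear in μ. The y-intercept is
the maintenance carbon spend at zero growth: converted to a substrate
uptake flux by dividing by (cdw_conv × carbons), pinned in FBA with
biomass fixed to zero and every other carbon exchange closed, the maximal
ATP-hydrolysis flux is the NGAM, installed as the hydrolysis reaction's
lower bound. The GAM is then the root (by bisection, to 0.01 mmol/gCDW on
a default [0, 200] bracket) of the summed growth-rate residuals, with each
observation pinning its measured substrate uptake *and* acetate secretion
fluxes; monotonicity of μ in GAM is checked before bisecting, and
per-observation residuals are reported because the model cannot fit all
observations simultaneously to zero.

The mM-C/OD600/h → mmol-C/gCDW/h conversion divides by a caller-supplied
CDW conversion factor (`cdw_conv`, mg/(OD600·mL)); on real data this
should be the CDW fit evaluated at the relevant growth rate (intercept
0.64 at μ = 0 for the NGAM step). This conversion is the single largest
judgment call in the procedure and is therefore an explicit argument
everywhere rather than a buried constant; the synthetic pipeline uses the
constant the generator used.

## Gap-filling and phenotype comparison

Gap-filling solves min Σyⱼ over binary indicators yⱼ for candidate
reactions, subject to Sv = 0, bounds, |vⱼ| ≤ M·yⱼ (M = 1000 mmol/gCDW/h)
and a biomass floor, with HiGHS branch-and-bound (`scipy.optimize.milp`)
— so minimality is *proven*, not heuristic; at a solver time limit the
incumbent is returned flagged `optimal=False`. Ties between equally small
sets are broken toward lexicographically smaller reaction ids by
infinitesimal objective weights. Numerical choice that matters: the
MILP's internal biomass floor is max(threshold, 0.1) /h, because a floor
near the solver's integrality tolerance would let an indicator sit at
y = v/M ≈ 1e-9–1e-6 and be rounded to zero, silently dropping a needed
reaction and corrupting the cardinality proof; the chosen set is then
verified by a plain LP at the user threshold (default 1e-6 /h, the
in-silico definition of "growth"). Candidate reversibility comes from the
database entries. Permanent exchange reactions are added only for
experimentally verified carbon sources; phenotype tests on other
substrates use transient exchanges that are discarded afterwards.

The in vivo growth call is ΔOD600 ≥ 0.9 (inclusive) within 20 h, with
linear interpolation between readings since plates are read about daily.
In silico calls are evaluated under three transport modes per substrate:
existing transporters only; plus a reversible uncatalyzed outer-membrane
diffusion into the periplasm; plus additionally an inner-membrane
diffusion into the cytoplasm. Uptake through the transient exchange is
capped at 10 mmol/gCDW/h (a plate normalizes carbon concentration, but
FBA needs a rate; the cap is configurable). Diffusion reactions are plain
transfers and never transform the substrate, so catabolism that requires
transporter-coupled chemistry (the sorbitol-like phosphorylating-
transporter class) correctly fails under direct cytoplasmic diffusion.
Mode monotonicity (cytoplasm ⊇ periplasm ⊇ transporter-only growth sets)
holds by construction because each mode only adds reactions.

## Growth-rate-dependent FBA

Plain fixed-point iteration: μₙ₊₁ = FBA optimum of the model whose
biomass reaction is rebuilt at μₙ. Because composition varies slowly with
growth rate the map is a mild contraction; convergence tolerance defaults
to 1e-4 /h with a 50-iteration cap, and an optional damping factor (off
by default) exists for oscillatory cases. The full trajectory is
reported, and the fixed point is independent of the initial guess on
every fixture. Flux comparison between two solutions uses
100·|vₐ−v_b|/max(|vₐ|,|v_b|) per reaction (0 when both magnitudes are
below 1e-9); because individual optimal fluxes are not unique, only
summary fractions (share of reactions differing ≥ 20%) are asserted.

## The synthetic toy network

The generators' defaults *are* the study conditions of the tests; they
were chosen once, for physiological plausibility and non-degeneracy, and
are not tuned per test.

Structure (21 reactions, 19 metabolites, three compartments): for each
substrate, an exchange, outer-membrane diffusion, an inner-membrane
transporter and a lumped catabolic reaction to a one-carbon precursor
pool; shared respiration (1 precursor C + 2 ADP + 2 Pᵢ → CO₂ + 2 ATP,
capacity 10 mmol C/gCDW/h), an acetate-overflow branch (3 precursor C →
acetate(2C) + CO₂ + 2 ATP), an uncoupled oxidation (precursor C → CO₂, no
ATP — energy spilling, idle at any growth optimum but necessary so that
pinned-flux fits can shed excess carbon), transport/exchange for acetate,
CO₂, water and protons, an ATP-hydrolysis maintenance reaction
(lower bound = NGAM) and a biomass reaction (40 mmol precursor C/gCDW +
GAM ATP).

Defaults: a fast 6-carbon substrate (uptake cap 10 mmol/gCDW/h) and a
slow one (cap 2), both yielding 12 ATP per molecule when fully respired;
GAM 20 mmol/gCDW, NGAM 5 mmol/gCDW/h; CDW conversion 0.5 mg/(OD600·mL).
Under these conditions FBA grows at 1.036 /h on the fast substrate with
acetate overflow (respiration saturates) and 0.190 /h on the slow one
without — reproducing the qualitative overflow asymmetry the maintenance
procedure relies on. Two deliberate structural choices:

- *Overflow is emergent, not prescribed.* Acetate excretion arises from
  the respiration capacity cap; a prescribed excretion fraction could not
  simultaneously satisfy the network's steady-state balance and the batch
  simulator.
- *Uniform energy yield.* Every ATP is made at 2 ATP per carbon burned
  (respiration and overflow alike; no direct substrate-level ATP at
  default yields). This makes the carbon-utilization-vs-μ relation
  exactly linear, so the slope/intercept → GAM/NGAM procedure is exact on
  noiseless data and the 5%-recovery test measures noise propagation, not
  model misspecification. A substrate `atp_yield` above 2×carbons adds
  direct catabolic ATP and bends the line.

Batch series follow OD(t) = OD₀e^{μt} with substrate/acetate linear in OD
at the FBA yields (concentration change per OD = flux × cdw_conv / μ);
noise is multiplicative on OD (how turbidity errors behave) and additive
on concentrations and weights, seeded through `numpy.random.default_rng`
for bit-reproducibility. Default batch sampling is 8 points from
inoculation (OD 0.02) to OD 0.5, a typical exponential-phase HPLC
sampling density; default noise is 1% per channel. Composition
measurements are the fit values plus Gaussian noise (sd 0.01
mg/(OD600·mL)) with negative draws resampled; pellet weighings are exact
(the round-trip tests target algebra, not noise); plate curves are
logistic for growers (saturation OD 1.2, crossing the call threshold well
before 20 h) and a low drift (< 0.3) for non-growers, read every 12 h for
10 days.

What the generators do *not* emulate — and hence what passing tests do
not establish about real data: lag and stationary phases (exponential
only), secretion products other than acetate, carbon-storage compounds,
growth-rate-dependent osmolyte pools, expression-weighted codon usage,
plate-edge and condensation artifacts, and any deviation from perfect
exponential balanced growth. Parameter recovery on the toy network
validates the inference machinery, not the biology of any particular
organism.

## Problem sizes and runtime

All tests run on desk-scale fixtures: LPs with ≤ 25 reactions, MILPs with
≤ 12 candidates (checked against exhaustive subset search), 1000-record
property sweeps, and fixed-point iterations of a handful of LP solves.
The full suite completes in a few seconds; the acceptance script in under
a second.

## Known limitations

- Flux variability, thermodynamic/loop-law constraints, gene–protein–
  reaction rules and knockouts are out of scope.
- The gap-filler is cardinality-parsimonious only; no sequence-evidence
  or likelihood weighting of candidates.
- `alpha_regression` assumes error-free dry weights (OLS of y on x).
- The maintenance unit conversion uses a single CDW factor per analysis;
  a growth-rate-dependent conversion must be applied by the caller per
  step if desired.
- tRNA/mRNA are not resolved separately from rRNA-derived RNA
  stoichiometry; ions are a single lumped species; no potassium
  counterion is added for glutamate.
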