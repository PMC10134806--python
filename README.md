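# marinegem

Curation toolkit for genome-scale metabolic models (GSMMs) of marine
heterotrophic bacteria.

Reconstructing a metabolic model for a marine bacterium runs into problems
that models of *E. coli*-like organisms never meet, almost all of them
caused by seawater-level salt (~0.3–0.4 M NaCl): cells lyse when washed in
water, so the OD600-to-dry-weight conversion factor needs a salt-corrected
protocol; the cell accumulates large osmolyte pools (glutamate) that belong
in the biomass reaction; and maintenance energetics must be inferred from
batch cultures because wild marine isolates rarely tolerate chemostats.
`marinegem` implements that curation workflow as a tested, reusable
library — together with a synthetic-data module that generates every input
the pipeline consumes, so the whole analysis runs end-to-end on a toy
network with known ground truth and no downloads.

## What it computes

**Flux balance analysis** (`model_core`). A model is a stoichiometric
matrix *S*, bounds and an objective; FBA solves the linear program

```
max  cᵀv    s.t.   S v = 0,   v_min ≤ v ≤ v_max
```

with SBML (Level 3 + fbc) input/output. Uptake is negative flux through an
exchange reaction; the biomass reaction's flux is the growth rate μ (1/h).

**Salt-corrected cell dry weight** (`cdw`). For a pellet with dry weight
*x*, wet weight *y*, harvested amount *w* (OD600·mL), wash salinity ρ
(mg NaCl/mg water) and assumed cellular water β (mg/mg CDW), the
water/salt mass balance gives the conversion factor

```
α = (x(1+ρ) − ρy) / (w(1 − ρβ))      [mg CDW / (OD600·mL)]
```

which is only weakly dependent on the assumed β. Plotting *y* against *x*
across aliquots with different added-back wash volumes estimates ρ from
the slope and α from the x-intercept as a cross-check.

**Growth-rate-dependent biomass composition** (`composition`). RNA,
protein and CDW per OD600·mL are linear in growth rate; dividing the lines
yields mass fractions at any μ, osmolytes (glutamate 5% of CDW) are added,
and the unquantified remainder (DNA, LPS, lipids, murein, ions, soluble
pools) is scaled from an *E. coli*-like reference while keeping its
internal proportions. Monomer stoichiometries come from the genome:
amino-acid frequencies from translated CDS, RNA nucleotides from rRNA
genes, DNA nucleotides from the whole genome.

**Maintenance energetics** (`maintenance`). Substrate and acetate
concentrations regressed against OD give consumption/excretion yields;
(consumption − excretion) × μ is the carbon utilization rate. Across
substrates it is linear in μ: the y-intercept, fed into FBA (maximize ATP
hydrolysis at zero biomass flux), gives the non-growth-associated
maintenance (NGAM); the growth-associated maintenance (GAM) is bisected so
FBA-predicted growth under the measured uptake/secretion fluxes matches
observation.

**Gap-filling and phenotypes** (`gapfill_phenotype`). A mixed-integer
program adds the provably minimum number of database reactions that let
the biomass reaction carry flux on a medium. Plate curves are called as
growth when ΔOD600 ≥ 0.9 within 20 h; in silico calls are compared under
three transport assumptions (existing transporters only, free diffusion
into the periplasm, free diffusion into the cytoplasm).

**Growth-rate-dependent FBA** (`grfba`). Fixed-point iteration: rebuild
the biomass reaction at the guessed μ, run FBA, feed the predicted μ back
until input and output agree — with a flux-distribution comparator.

## Worked example

Infer maintenance parameters from two simulated batch cultures on the toy
network (true GAM 20 mmol/gCDW, NGAM 5 mmol/gCDW/h, 1% measurement noise):

```python
from marinegem.synthetic_data import ToyNetworkSpec, make_toy_model, SimConfig, simulate_batch
from marinegem.maintenance import estimate_maintenance, SubstrateInfo

spec = ToyNetworkSpec()
model = make_toy_model(spec)
series = [simulate_batch(spec, name, SimConfig(seed=s))
          for s, name in ((1, "glc"), (2, "gal"))]
info = {"glc": SubstrateInfo("EX_glc", 6), "gal": SubstrateInfo("EX_gal", 6)}
params = estimate_maintenance(model, series, cdw_conv=0.5, substrate_info=info)
print(f"NGAM = {params.ngam:.3f} mmol ATP/gCDW/h")
print(f"GAM  = {params.gam:.3f} mmol ATP/gCDW")
```

prints

```
NGAM = 4.985 mmol ATP/gCDW/h
GAM  = 19.412 mmol ATP/gCDW
```

i.e. both parameters recovered within 3% of the generator truth. The
fast substrate saturates the toy's respiratory capacity and overflows
acetate (which the yield analysis subtracts); the slow substrate does not —
the spread of growth rates is what makes the intercept/slope decomposition
identifiable. Growth-rate-dependent FBA on the same network:

```python
from marinegem.grfba import gr_fba
from marinegem.composition import reference_fits
from marinegem.synthetic_data import toy_biomass_builder

res = gr_fba(model, toy_biomass_builder(spec, reference_fits()),
             {"EX_glc": (0.0, 1000.0), "EX_gal": (-2.0, 1000.0)}, gr0=0.01)
print(f"fixed point {res.fixed_point_gr:.4f} /h in {res.iterations} iterations")
```

converges to `0.1845 /h in 3 iterations` — the same fixed point from
initial guesses 0.01 and 1.0.

A thin CLI covers the file-based entry points:

```bash
marinegem stats model.xml                      # reaction/metabolite census
marinegem fba model.xml --medium medium.yaml   # objective + nonzero fluxes
marinegem cdw regress pellets.csv              # (rho, alpha) from add-back series
marinegem simulate batch --substrate glc --seed 1 --out glc.csv
marinegem maintenance --model model.xml --series glc=glc.csv --series gal=gal.csv \
    --substrate glc=EX_glc:6 --substrate gal=EX_gal:6 --cdw-conv 0.5
```

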