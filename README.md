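# mangrove-growth

Growth of planted *Rhizophora apiculata* mangrove forest under salinity,
crowding, inundation and heavy-metal stress — a gap-model analysis toolkit
for plantation inventories, sediment geochemistry, and pollution-scenario
simulation.

Mangroves take up and store heavy metals, which makes them attractive as a
natural phytoremediation system — but the same metals suppress their
growth. This package quantifies that trade-off for an even-aged planted
forest where stand ages are known, using:

* a **Botkin/JABOWA growth core**: diameter growth
  `d(dbh)/dt = Gopt·MUL · dbh(1 − dbh·H/(Dmax·Hmax)) / (2b1 + 3b2·dbh − 4b3·dbh²)`
  with height curve `H = b1 + b2·dbh − b3·dbh²` and trunk biomass
  `Biom = a1·dbh^c1`;
* a **growth multiplier** `MUL ∈ [0,1]`, the product of a decreasing sigmoid
  in pore-water salinity, a decreasing sigmoid in tree density, a
  rise–plateau–fall response to ground elevation, and a hormetic
  two-threshold dose-response `P(x) = (1 − e^{−(x/th1)^{α1}})·e^{−(x/th2)^{α2}}`
  to root-tissue metal concentration;
* **exact growth-rate extraction**: the ODE is separable, so the lifetime
  rate G of a stand follows from (dbh at planting, dbh at age, age) by
  quadrature — `G = ∫ du/φ(u) / age`;
* **nonlinear estimation** of the multiplier parameters from extracted G
  values (bounded multi-start least squares, stratified fit/hold-out
  splits, delta-method confidence bands), and dbh validation on hold-out
  plots;
* **enrichment-factor geochemistry**: EF = (Me/Fe)_sample/(Me/Fe)_background
  against continental-shale background, classified at 1.5 and 5;
* a **raster scenario engine** (ESRI ASCII grids, 1-ha stands, cohort-exact
  life cycle with recruitment and slow-growth mortality) comparing trunk
  biomass 1978–2020 under no (SC0), observed (SC0P1) and doubled (SC0P2)
  chromium load;
* **synthetic-data generators** and the transcribed 11-site survey tables,
  so every stage runs and is tested without external data.

## Worked example

```python
import numpy as np
from mangrove_growth import (
    load_params, grow_tree, extract_G, combined_multiplier, Environment,
)

sp, mp, _ = load_params()          # packaged parameter set

# environment of a moderately stressed stand
env = Environment(salinity=12.4, density=42, elevation=0.2,
                  pollutant_conc={"Cr": 0.7})
mul = combined_multiplier(env, mp)
print(f"MUL = {mul:.3f}")          # MUL = 0.238

# grow a seedling for 32 years under that multiplier
traj = grow_tree(0.5, 32, sp, mul=mul)
print(f"dbh at 32 yr = {traj[-1]:.2f} cm")   # dbh at 32 yr = 7.45 cm

# invert: what lifetime growth rate does that observation imply?
print(f"G = {extract_G(0.5, traj[-1], 32, sp):.1f}")   # G = 95.3
# ... equal to Gopt * MUL = 400 * 0.238 by construction
```

The multiplier says this stand realises ~24% of optimal growth (salinity
just above its 11.3 ppt threshold costs the most); after 32 years the mean
tree reaches ~7.5 cm dbh, and the extraction recovers exactly the rate
the environment imposed — the identity the estimation pipeline is built on.

## Analysis scripts

`analysis/` contains the numbered drivers, each writing tables under
`results/`:

1. `01_heavy_metals.py` — survey statistics, enrichment factors,
   bioconcentration ratios for the 11 sampled stands.
2. `02_growth_rates.py` — lifetime growth rates of those stands, their
   salinity correlation, and the Cr dose-response fit.
3. `03_fit_validation.py` — synthetic 208-plot survey: fit on a 76-plot
   stratified subset, dbh validation on the 132 hold-out plots.
4. `04_scenarios.py` — the three-scenario biomass comparison on a 30×30
   synthetic landscape (totals, histograms, 2020 maps).

A CLI mirrors the pipeline for shell use:
`mangrove-growth synth|extract-g|fit|validate|summarize|ef|simulate --help`.

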