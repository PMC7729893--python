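# Methods

This note documents the model, its parameterisation, the synthetic data
used to exercise it, and the numerical and design choices behind the
implementation.

## Growth model

Single-tree growth follows the classical Botkin/JABOWA gap-model form.
The state variable is the diameter at breast height, `dbh` [cm]; height is
tied to diameter by the parabola

    H(dbh) = b1 + b2·dbh − b3·dbh²,
    b2 = 2(Hmax − b1)/Dmax,   b3 = (Hmax − b1)/Dmax²,

constructed so that H(0) = b1 (breast height, 137 cm), H(Dmax) = Hmax and
H′(Dmax) = 0. Diameter growth obeys

    d(dbh)/dt = G · dbh · (1 − dbh·H/(Dmax·Hmax)) / (2b1 + 3b2·dbh − 4b3·dbh²),

with G = Gopt·MUL. The right-hand side is positive on (0, Dmax) and zero at
both ends, so trajectories rise monotonically towards the asymptote Dmax;
dbh = 0 is a fixed point, which is why trees enter the model at a seedling
diameter dbh0 = 0.5 cm (configurable) rather than zero. Trunk dry biomass is
the power law `Biom = a1·dbh^c1` [kg].

## Environmental multipliers

MUL ∈ [0, 1] is a product of independent responses:

* **Salinity and density** (competition proxy) each use a decreasing sigmoid
  `g(x) = (1−a0)/(1 + e^{d(x−tr)}) + a0` with floor `a0 > 0` (growth never
  stops entirely), threshold `tr` (midpoint: g(tr) = (1+a0)/2) and steepness
  `d > 0`. Published estimates print the salinity slope with a negative
  sign; under this implementation's decreasing convention both slopes enter
  as |d|, which matches the observed negative correlation of growth with
  salinity and the fitted response surfaces.
* **Elevation** (a proxy for inundation frequency/duration) uses a
  rise–plateau–fall product
  `f(el) = (a1e + (amax−a1e)·R(el)) · (a2e + (1−a2e)·F(el))` with
  `R = 1 − exp(−((el−elmin)/el1)^α)` rising and
  `F = exp(−((el−elmin)/el2)^β)` falling, and f ≡ 0 below the viability
  limit elmin (default −1.0 m). The published functional form is not
  typographically recoverable; this surrogate honours its stated contract
  exactly: value a1e = 0.027 at elmin, limit amax·a2e = 0.11 at high
  elevation, and with the published constants a plateau of near-optimal
  values at roughly 0–0.45 m, inside the −0.5..0.5 m band where the species
  is observed to develop well. A negative printed scale length (el1 = −0.96)
  is read as |el1|.
* **Heavy metals** use the hormetic two-threshold response
  `P(x) = (1 − e^{−(x/th1)^{α1}}) · e^{−(x/th2)^{α2}}` on the root-tissue
  concentration x [mg/kg DW]: stimulation below th1, suppression beyond
  th2, P → 0 at high dose. Root rather than soil concentration is the dose
  variable because roots integrate the accumulation history. A metal absent
  from the environment contributes exactly 1 (unpolluted convention); for
  any x > 0 the literal formula is used even though P(0⁺) < 1 — the
  depressed growth at low measured concentrations is the hormesis
  signature, not an artefact. With several metals present the per-metal P
  values multiply.

## Parameter values

The multiplier constants shipped in `data/default_params.yaml` are the
published nonlinear-regression estimates for *R. apiculata* in Can Gio
(density a0 = 0.402741, d = 0.156347, tr = 66.9241 trees/plot; salinity
a0 = 0.21276, d = 0.4, tr = 11.348 ppt; elevation a1e = 0.027, el1 = 0.96,
α = 13.1, el2 = 1.48, β = 6.02, a2e = 0.11; Cu/Cr/Ni dose-response
thresholds as tabulated). Species constants are *not* part of that estimate
set and are this package's calibration: Hmax = 3000 cm, Dmax = 50 cm,
b1 = 137 cm, Gopt = 400, chosen so that (i) extracted lifetime growth rates
on the 11-stand inventory land in the reported O(150–400) range, and (ii) a
stressed 40-year tree reaches the observed 13–25 cm dbh (unstressed: ~39
cm). Note Gopt must exceed every observed G because G = Gopt·MUL ≤ Gopt.
Trunk allometry defaults to a1 = 0.235, c1 = 2.42, an Ong-type
*R. apiculata* stem allometry. All of these are config values, not built-in
truths.

## Growth-rate extraction

For a constant rate G the growth ODE is separable, so the lifetime rate
implied by growing from dbh0 to dbh_age in `age` years is

    G = [ ∫_{dbh0}^{dbh_age} du/φ(u) ] / age,

with φ the shape factor above. `extract_G` evaluates this by adaptive
quadrature — the exact inversion of the forward integrator, as the
round-trip property tests verify to 1e−4 relative (in practice ~1e−10).
Observations with dbh_age ≤ dbh0 return G = 0 with a warning (censored, no
observable growth); dbh_age ≥ Dmax is infeasible under the model and
raises.

## Parameter estimation

`fit_multipliers` minimises Σᵢ (Gᵢ − Gopt·MUL(envᵢ; θ))² with scipy's
bounded trust-region least squares, multi-started from 8 seeded draws
within the bounds (ties broken by RSS, then parameter norm). The default
free set is the two sigmoid triples plus Gopt; elevation and pollutant
parameters are held at their configured values, because inventory
covariates alone identify the 7-parameter elevation shape poorly and the
dose-response is estimated from the (much smaller) tissue-sampled subset
via `fit_pollutant`. Standard errors come from the delta method,
σ²(JᵀJ)⁻¹; 95% bands on the response surface are pointwise. Estimation/
hold-out splits (default 76/132 of 208) are stratified over terciles of
salinity × elevation × density so the fitting subset spans every gradient.
A constant covariate raises an error naming the offender. Validation
forward-predicts dbh at each hold-out plot's age and reports R² of
predicted vs observed.

## Enrichment factors

Sediment enrichment is classified by EF = (Me/Fe)_sample / (Me/Fe)_background
with continental-shale background (Fe 47,200, Cu 45, Cr 90, Ni 68 mg/kg —
a conventional, explicitly overridable reference): EF < 1.5 natural,
1.5 ≤ EF ≤ 5 anthropogenic, EF > 5 significant. Summary statistics use the
sample (n−1) standard deviation, which is the convention that reproduces
the printed regional values; rounding happens only at presentation. The
printed 11-site table does not include Fe, so the package ships a
synthetic soil-Fe column (`fe_soil_synthetic.csv`, clearly labelled)
reverse-engineered from the published per-site Cu enrichment factors; it is
internally consistent (forward computation reproduces the published Cu, Cr
and Ni factors to 2 decimals) but it is a fixture, not data. Two printed
summary cells of the source table (the Thi Vai "min" and "std" rows, which
repeat a site row instead of the column minima) are internally inconsistent
with the listed site values and are excluded from every assertion.

## Stand simulator

The scenario engine advances 1-ha raster cells through a simplified annual
life cycle: establishment only at initialisation (every forested cell gets
N ~ U{10..115} seedlings per 100 m² plot, ×100 plots per cell), growth of
every tree under the cell-local MUL (the density response consumes the
cell's current per-plot density, closing the competition feedback),
recruitment R ~ Poisson(f·adults) capped by the density ceiling, and
mortality = background m0 plus JABOWA-style slow-growth mortality (0.368/yr
once the annual increment stays below 0.05 cm for k = 2 consecutive years).
Defaults: m0 = 0.01/yr, f = 0.05/adult/yr, adult threshold 5 cm dbh,
ceiling 115/plot; all in config. No thinning or other disturbance follows
establishment. The full life-cycle equation system of the antecedent
mangrove dynamics model is published elsewhere and is deliberately not
reproduced here; this cycle is a documented simplification.

Because all trees recruited into a cell the same year stay identical under
deterministic growth, trees are tracked as cohorts (dbh, count) — an exact
aggregation of the individual-based model that keeps a 30×30 × 42-yr run
with ~6000 trees per cell below a second. Annual integration in the
simulator (and the inventory generator) is a fixed-step classical RK4 with
4 steps/yr, vectorised over all cohorts; against the adaptive integrator
the error is below 1e−5 relative, far under measurement precision. The
single-tree API (`grow_tree`) uses scipy's adaptive RK45 with rtol 1e−9.

Scenarios differ only in the scaling of the static root-Cr layer: SC0
(scale 0, the pollutant response is exactly 1), SC0P1 (observed load) and
SC0P2 (doubled concentration field — the field, not the multiplier).
Totals are Σ cells (kg/ha × area weight)/1000 tons, linear in the weight.

## Synthetic data: what it emulates, what it does not

The inventory generator draws covariates uniformly on the survey's ranges
(salinity 8–18.2 ppt, elevation −0.5..0.5 m, density 10–115/plot, ages
19–40 yr), grows each plot's mean tree under the true parameters and
applies multiplicative lognormal noise (σ = 5% default — the level at which
hold-out dbh validation lands in the high-R² regime a usable model needs;
the field survey reports no noise model). The raster generator produces
low-pass-filtered Gaussian noise rescaled to physical ranges; the root-Cr
range (20–150 mg/kg) is chosen so the load spans the hormetic plateau into
the declining branch of the Cr response — the regime the published
scenario contrast implies — since the true maps are not deposited.

Consequences: passing tests demonstrate internal consistency (round trips,
recovery of generating parameters, scenario ordering and histogram shift),
not agreement with the real landscape. Absolute biomass totals depend on
the undeposited maps, the species calibration and the simplified life
cycle, and are reported as magnitudes with an ordering claim only. The
generator also omits spatial autocorrelation of plot covariates,
measurement error in the covariates themselves, and any feedback of trees
on their environment.

## Numerical choices and degenerate inputs

* Quadrature and root-free extraction make extract_G deterministic; its
  integrand diverges logarithmically at Dmax, hence the explicit
  infeasibility error there.
* Sigmoid exponents are clipped at ±700 to avoid overflow on absurd inputs;
  multiplier outputs are clipped to [0, 1] against rounding.
* RK4 overshoot past Dmax is clamped; trajectories are non-decreasing and
  bounded by construction.
* Multi-start least squares is seeded and fully deterministic; optimiser
  ties are broken by (RSS, ‖θ‖).
* All randomness flows through explicitly passed integer seeds
  (numpy Generator); identical seed + config gives bit-identical outputs,
  including across the CLI.
* Fixture CSVs are checksum-guarded; a corrupted file raises rather than
  silently loading.

## Known limitations

* Competition acts only through the density multiplier; there is no light
  or size-structured competition, so dense stands of large trees can reach
  per-hectare biomasses above empirical self-thinning limits. Histogram
  *shapes* and scenario *ordering* are the supported conclusions.
* The pollutant dose-response fitted from 11 stands is weakly identified
  (the analysis driver prints this); the shipped constants should be used
  unless a larger tissue-sampled inventory is available.
* One static environment per cell/plot: no salinity seasonality, sea-level
  change, sedimentation, or metal transport dynamics.
* Monospecific stands only.
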