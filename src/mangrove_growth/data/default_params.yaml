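# Default parameter set for Rhizophora apiculata growth under environmental
# stress in the Can Gio mangrove forest.
#
# Multiplier constants are the published nonlinear-regression estimates from
# the Can Gio inventory.  Sign convention: both sigmoid responses (salinity,
# density) DECREASE with their covariate; the source table prints the
# salinity slope as -0.4 and the elevation scale el1 as -0.96, which are read
# here as |d| = 0.4 and |el1| = 0.96 under the decreasing/positive-scale
# convention.
#
# Species constants (Hmax, Dmax, Gopt, b1, biomass allometry) are not part of
# the published estimate set; these defaults are calibrated so an unstressed
# 40-year tree reaches ~25 cm dbh and extracted growth rates G fall in the
# observed O(150-400) range.  Override freely.

species:
  Hmax: 3000.0        # cm
  Dmax: 50.0          # cm
  b1: 137.0           # cm (breast-height convention)
  Gopt: 400.0         # Botkin growth constant, cm units
  a1_biom: 0.235      # trunk biomass allometry Biom = a1 * dbh^c1 [kg]
  c1_biom: 2.42

multipliers:
  density:            # x in trees / 100 m^2 plot
    a0: 0.402741
    d: 0.156347
    tr: 66.9241
  salinity:           # x in ppt pore-water salinity (printed slope: -0.4)
    a0: 0.21276
    d: 0.4
    tr: 11.348
  elevation:          # el in metres (printed el1: -0.96)
    a1e: 0.027
    el1: 0.96
    alpha: 13.1
    el2: 1.48
    beta: 6.02
    a2e: 0.11
    amax: 1.0
    elmin: -1.0
  pollutant:          # x in mg/kg root dry weight
    Cu: {th1: 3.28, th2: 54.47, alpha1: 0.68, alpha2: 0.81}
    Cr: {th1: 1.89, th2: 170.25, alpha1: 0.12, alpha2: 1.69}
    Ni: {th1: 0.53, th2: 105.43, alpha1: 0.06, alpha2: 2.53}

# Simplified stand life cycle (establishment - growth - competition -
# reproduction - mortality).  Competition acts only through the density
# multiplier; mortality is background plus JABOWA-style slow-growth
# mortality after k consecutive years of increment below the threshold.
lifecycle:
  dbh0: 0.5                  # cm, dbh at planting/recruitment
  m0: 0.01                   # 1/yr background mortality
  fecundity: 0.05            # expected recruits per adult per yr (Poisson)
  adult_dbh: 5.0             # cm, minimum dbh to reproduce
  slow_growth_threshold: 0.05  # cm/yr increment below which a year counts slow
  slow_growth_years: 2       # k consecutive slow years trigger stress mortality
  stress_mortality: 0.368    # 1/yr extra mortality while stressed
  density_ceiling: 115       # max trees per 100 m^2 plot (recruitment cap)

# Enrichment-factor background: continental shale averages
# (Turekian & Wedepohl 1961), Fe-normalised.  mg/kg.
background:
  source: continental shale (Turekian & Wedepohl 1961)
  reference: Fe
  values:
    Fe: 47200.0
    Cu: 45.0
    Cr: 90.0
    Ni: 68.0
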