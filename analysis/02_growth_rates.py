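#!/usr/bin/env python
"""Lifetime growth rates of the 11 sampled stands and their environmental
correlates, including the hormetic dose-response of growth to root metals.

Extracts G from each stand's (mean dbh, age) under the packaged species
calibration, correlates it with pore-water salinity, and fits the
two-threshold pollutant response to root-Cr concentrations.  Writes
results/growth_rates_11_plots.csv and results/pollutant_fit_cr.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mangrove_growth.extraction import extract_G_frame, fit_pollutant
from mangrove_growth.multipliers import (
    combined_multiplier_fields,
    pollutant_multiplier,
)
from mangrove_growth.params import load_params
from mangrove_growth.synthetic import load_reference_tables

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    sp, mp, _ = load_params()
    hm, plots = load_reference_tables()

    plots = plots.copy()
    plots["G_extracted"] = extract_G_frame(plots, sp)
    plots.round(3).to_csv(RESULTS / "growth_rates_11_plots.csv", index=False)

    r_ext = np.corrcoef(plots["salinity"], plots["G_extracted"])[0, 1]
    r_rep = np.corrcoef(plots["salinity"], plots["G_reported"])[0, 1]
    print(f"G vs salinity: r = {r_ext:.2f} (extracted), {r_rep:.2f} (reported) "
          "- growth declines along the salinity gradient.")
    print("Note: extracted G uses this package's species calibration, so its "
          "scale differs from the reported column; the ordering and the "
          "salinity correlation are the comparable features.")

    # hormetic response of growth to root Cr at the 11 stands: normalise the
    # extracted G by the salinity/density part of the multiplier product
    # (elevation was not reported per stand; the plateau value is assumed)
    root_cr = (hm[(hm.compartment == "root") & (hm.metal == "Cr")]
               .set_index("site")["conc"])
    x = root_cr.loc[plots["plot_id"]].to_numpy()
    base = sp.Gopt * combined_multiplier_fields(
        plots["salinity"].to_numpy(), plots["density"].to_numpy(),
        np.full(len(plots), 0.15), mp)
    response = np.clip(plots["G_extracted"].to_numpy() / base, 0.0, 1.0)
    est = fit_pollutant(x, response, "Cr", p0=mp.pollutants["Cr"], seed=0)
    grid = np.logspace(-1, 2.5, 50)
    pd.DataFrame({
        "root_cr_mg_kg": grid,
        "P_fitted": pollutant_multiplier(grid, est),
        "P_reference": pollutant_multiplier(grid, mp.pollutants["Cr"]),
    }).round(4).to_csv(RESULTS / "pollutant_fit_cr.csv", index=False)
    print(f"Cr dose-response fit on 11 stands: th1 = {est.th1:.2f}, "
          f"th2 = {est.th2:.1f} mg/kg (reference 1.89 / 170.25); with n = 11 "
          "the thresholds are weakly identified - the shape, not the point "
          "estimates, is the result.")


if __name__ == "__main__":
    main()
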