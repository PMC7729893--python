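"""Environmental growth-multiplier functions.

Optimal diameter growth is scaled by a dimensionless multiplier MUL in
[0, 1], the product of independent responses to pore-water salinity, tree
density (competition), ground elevation (a proxy for inundation frequency
and duration) and root-accumulated heavy-metal load.  All functions accept
scalars or numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .params import (
    Environment,
    ElevationMultiplierParams,
    MultiplierParams,
    PollutantMultiplierParams,
    SigmoidMultiplierParams,
)

__all__ = [
    "sigmoid_multiplier",
    "elevation_multiplier",
    "pollutant_multiplier",
    "combined_multiplier",
    "combined_multiplier_fields",
]


def sigmoid_multiplier(x, p: SigmoidMultiplierParams):
    """Decreasing sigmoid response, g(tr) = (1 + a0)/2 at the threshold.

    g(x) = (1 - a0) / (1 + exp(d (x - tr))) + a0, bounded in (a0, 1).
    """
    x = np.asarray(x, dtype=float)
    z = np.clip(p.d * (x - p.tr), -700.0, 700.0)  # avoid exp overflow far out
    out = (1.0 - p.a0) / (1.0 + np.exp(z)) + p.a0
    return out if out.ndim else float(out)


def elevation_multiplier(el, p: ElevationMultiplierParams):
    """Rise-plateau-fall elevation response; zero below the viability limit.

    f(el) = (a1e + (amax - a1e) R) * (a2e + (1 - a2e) F) for el >= elmin,
    with R = 1 - exp(-((el-elmin)/el1)^alpha) and
    F = exp(-((el-elmin)/el2)^beta); f = 0 for el < elmin.
    """
    el = np.asarray(el, dtype=float)
    s = np.maximum(el - p.elmin, 0.0)
    rise = 1.0 - np.exp(-((s / p.el1) ** p.alpha))
    fall = np.exp(-((s / p.el2) ** p.beta))
    f = (p.a1e + (p.amax - p.a1e) * rise) * (p.a2e + (1.0 - p.a2e) * fall)
    out = np.where(el < p.elmin, 0.0, f)
    return out if out.ndim else float(out)


def pollutant_multiplier(x, p: PollutantMultiplierParams):
    """Hormetic dose response: stimulation below th1, suppression above th2.

    P(x) = (1 - exp(-(x/th1)^alpha1)) * exp(-(x/th2)^alpha2), in [0, 1],
    unimodal with P -> 0 at high dose.  Absence of the pollutant is handled
    by the caller (contribution 1), not by evaluating P(0).
    """
    x = np.asarray(x, dtype=float)
    out = (1.0 - np.exp(-((x / p.th1) ** p.alpha1))) * np.exp(-((x / p.th2) ** p.alpha2))
    return out if out.ndim else float(out)


def combined_multiplier(env: Environment, mp: MultiplierParams) -> float:
    """Product multiplier MUL in [0, 1] for a single environment.

    MUL = g_sal(salinity) * g_dens(density) * f(elevation) * prod_m P_m(x_m),
    where the pollutant product runs over metals present in the environment
    (each absent metal contributes 1, the unpolluted convention).
    """
    mul = (
        sigmoid_multiplier(env.salinity, mp.salinity)
        * sigmoid_multiplier(env.density, mp.density)
        * elevation_multiplier(env.elevation, mp.elevation)
    )
    if env.pollutant_conc:
        for metal, x in env.pollutant_conc.items():
            if metal not in mp.pollutants:
                raise KeyError(f"no pollutant response configured for {metal!r}")
            mul *= pollutant_multiplier(x, mp.pollutants[metal])
    return float(np.clip(mul, 0.0, 1.0))


def combined_multiplier_fields(salinity, density, elevation, mp: MultiplierParams,
                               pollutant_conc: dict | None = None):
    """Vectorised :func:`combined_multiplier` over aligned arrays.

    ``pollutant_conc`` maps metal name to an array of root concentrations
    aligned with the other fields; omit it (or a metal) for the unpolluted
    case.
    """
    mul = (
        sigmoid_multiplier(salinity, mp.salinity)
        * sigmoid_multiplier(density, mp.density)
        * elevation_multiplier(elevation, mp.elevation)
    )
    if pollutant_conc:
        for metal, x in pollutant_conc.items():
            mul = mul * pollutant_multiplier(x, mp.pollutants[metal])
    return np.clip(mul, 0.0, 1.0)
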